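"""3D on-lattice agent-based engine for cancer / CD8+ T-cell dynamics.

Agents live on a cubic lattice of 10 um voxels: a T cell occupies one voxel,
a cancer cell an axis-aligned 2x2x2 block.  Adjacency is the Moore
(26-neighbour) relation between any voxel of one agent and any voxel of
another.  Each time step of ``dt_hours`` executes a fixed sub-phase order:

    recruitment -> IL-2 secretion/diffusion/decay -> contact actions
    (activation, kill attempts, PDL1 induction, suppression) -> divisions
    -> migrations -> deaths and clearance

with agents processed in a uniformly re-shuffled order inside each
sub-phase.  All randomness flows from per-subsystem streams spawned from one
seed, so identical seeds give bit-identical trajectories.

Rules in brief: effector T cells activate deterministically on first cancer
contact and become cytotoxic; a cytotoxic cell makes one kill attempt per
step against one uniformly chosen adjacent living cancer cell (probability
``p_kill_neg`` / ``p_kill_pos`` by target PDL1 state); a PDL1- target
surviving an attempt converts to PDL1+ with probability
``p_pdl1_induction`` (irreversibly); a cytotoxic cell adjacent to a PDL1+
cell is suppressed with probability ``p_supp`` per step (rescaled under
anti-PDL1 treatment) and takes no further offensive action.  Non-suppressed
cells divide when their cycle cooldown elapses and a free adjacent site
exists, T cells additionally requiring local IL-2 above the division
threshold; cells migrate as blind random walks at their configured speed.
Dead cancer cells keep occupying their block for ``dead_clearance_time_h``
before the voxels are freed.  Cancer cells also carry a small spontaneous
death hazard (tumour turnover); dead cells from any cause feed the
antigen-release signal that drives effector recruitment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from . import _kernels, treatment as treatment_mod, vasculature as vasc_mod
from .config import (
    CANCER_DEAD,
    CANCER_EDGE_VOXELS,
    CANCER_PDL1_NEG,
    CANCER_PDL1_POS,
    RunConfig,
    T_CYTOTOXIC,
    T_EFFECTOR,
    T_SUPPRESSED,
)
from .cytokine import CytokineField
from .errors import ConfigurationError, IntegrityError

_TS_COLUMNS = [
    "step",
    "time_h",
    "time_d",
    "cancer_pdl1_neg",
    "cancer_pdl1_pos",
    "cancer_dead",
    "t_effector",
    "t_cytotoxic",
    "t_suppressed",
    "il2_total",
]

_EVENT_COLUMNS = [
    "step",
    "recruits",
    "forfeited_recruits",
    "activations",
    "kill_attempts",
    "kills",
    "inductions",
    "suppressions",
    "spontaneous_deaths",
    "cancer_divisions",
    "t_divisions",
    "blocked_divisions",
    "t_deaths",
    "cleared",
    "moves",
    "blocked_moves",
]


def agent_size(state_code: int) -> int:
    return CANCER_EDGE_VOXELS if state_code <= CANCER_DEAD else 1


@dataclass
class Snapshot:
    """Voxel-level record of the simulation at one time point."""

    day: float
    clock_h: float
    labels: np.ndarray        # uint8 state codes, N^3
    il2: np.ndarray           # float64 concentrations, N^3
    ids: np.ndarray           # int32 agent ids (-1 empty), N^3
    voxel_size_um: float
    seed: int | None = None
    config_hash: str | None = None
    schema_version: int = 1


class Simulation:
    """One seeded realisation of the tumour-immune lattice model."""

    def __init__(self, config: RunConfig, seed: int, seed_tumor: bool = True):
        config.validate()
        self.config = config
        self.seed = int(seed)
        lat = config.lattice
        self.n = lat.n_voxels_per_edge
        self.dt_h = lat.dt_hours
        self.voxel_um = lat.voxel_size_um

        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(4)
        self._rng_abm = np.random.default_rng(kids[0])
        self._rng_recruit_count = np.random.default_rng(kids[1])
        self._rng_recruit_place = np.random.default_rng(kids[2])
        self._rng_vasc = np.random.default_rng(kids[3])

        self.vasculature = vasc_mod.place_entry_points(
            lat,
            config.rules.lambda_vasc_per_um,
            self._rng_vasc,
            base_density=config.rules.base_entry_density,
        )
        self.field = CytokineField.zeros(
            self.n, config.cytokine, dx_um=self.voxel_um, dt_abm_h=self.dt_h
        )

        # agent registry (struct-of-arrays, geometric growth)
        cap = 1024
        self.state = np.zeros(cap, np.uint8)
        self.ax = np.zeros(cap, np.int64)
        self.ay = np.zeros(cap, np.int64)
        self.az = np.zeros(cap, np.int64)
        self.cooldown = np.zeros(cap, np.float64)
        self.age = np.zeros(cap, np.float64)
        self.divisions = np.zeros(cap, np.int64)
        self.death_time = np.full(cap, np.inf)
        self.alive = np.zeros(cap, bool)
        self.n_agents = 0

        self.occ = np.full((self.n, self.n, self.n), -1, np.int32)
        self.clock_h = 0.0
        self.step_index = 0
        self.cumulative_dead_cancer = 0  # all cancer deaths (kills + spontaneous)
        self.cumulative_kills = 0        # T-cell kills only
        self._ts_rows: list[list] = []
        self._event_rows: list[list] = []

        if seed_tumor:
            self._place_seed_cell()
        self._record(initial=True)

    # ------------------------------------------------------------------ #
    # construction helpers

    def _place_seed_cell(self) -> None:
        c = self.n // 2 - 1
        if c < 0 or c + CANCER_EDGE_VOXELS > self.n:
            raise ConfigurationError("lattice too small for the seed cancer block")
        self.add_agent(CANCER_PDL1_NEG, (c, c, c))

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_agents + extra
        cap = self.state.size
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("state", "ax", "ay", "az", "cooldown", "age",
                     "divisions", "death_time", "alive"):
            old = getattr(self, name)
            new = np.zeros(cap, old.dtype)
            if name == "death_time":
                new[:] = np.inf
            new[: old.size] = old
            setattr(self, name, new)

    def add_agent(self, state_code: int, anchor) -> int:
        """Place a new agent; used at init, recruitment and by tests."""
        x, y, z = (int(v) for v in anchor)
        sz = agent_size(state_code)
        if not (0 <= x <= self.n - sz and 0 <= y <= self.n - sz and 0 <= z <= self.n - sz):
            raise ConfigurationError(f"anchor {anchor} does not fit on the lattice")
        block = self.occ[x : x + sz, y : y + sz, z : z + sz]
        if (block >= 0).any():
            raise IntegrityError(f"anchor {anchor} collides with an existing agent")
        self._ensure_capacity(1)
        i = self.n_agents
        self.state[i] = state_code
        self.ax[i], self.ay[i], self.az[i] = x, y, z
        self.cooldown[i] = (
            self.config.rules.cancer_cycle_time_h
            if state_code <= CANCER_DEAD
            else self.config.rules.t_cell_cycle_time_h
        )
        self.age[i] = 0.0
        self.divisions[i] = 0
        self.death_time[i] = np.inf
        self.alive[i] = True
        block[...] = i
        self.n_agents += 1
        return i

    # ------------------------------------------------------------------ #
    # queries

    @property
    def t_days(self) -> float:
        return self.clock_h / 24.0

    def counts(self) -> np.ndarray:
        """Live-agent counts indexed by state code (length 7)."""
        return np.bincount(self.state[: self.n_agents][self.alive[: self.n_agents]],
                           minlength=7)

    def label_volume(self) -> np.ndarray:
        lab = np.zeros_like(self.occ, dtype=np.uint8)
        m = self.occ >= 0
        lab[m] = self.state[self.occ[m]]
        return lab

    def snapshot(self) -> Snapshot:
        return Snapshot(
            day=self.t_days,
            clock_h=self.clock_h,
            labels=self.label_volume(),
            il2=self.field.grid.copy(),
            ids=self.occ.copy(),
            voxel_size_um=self.voxel_um,
            seed=self.seed,
            config_hash=self.config.hash(),
        )

    def check_consistency(self) -> None:
        """Full rescan: registry and occupancy index must agree exactly."""
        rebuilt = np.full_like(self.occ, -1)
        for i in range(self.n_agents):
            if not self.alive[i]:
                continue
            sz = agent_size(int(self.state[i]))
            x, y, z = self.ax[i], self.ay[i], self.az[i]
            if not (0 <= x <= self.n - sz and 0 <= y <= self.n - sz
                    and 0 <= z <= self.n - sz):
                raise IntegrityError(f"agent {i} block leaves the lattice")
            blk = rebuilt[x : x + sz, y : y + sz, z : z + sz]
            if (blk >= 0).any():
                raise IntegrityError(f"agent {i} overlaps agent {blk.max()}")
            blk[...] = i
        if not np.array_equal(rebuilt, self.occ):
            raise IntegrityError("occupancy index does not match the agent registry")

    # ------------------------------------------------------------------ #
    # sub-phases (public so each rule can be exercised in isolation)

    def recruit(self) -> tuple[int, int]:
        """Poisson arrivals of effector T cells at free entry voxels.

        The arrival count is an inverse-CDF draw from a dedicated uniform
        stream, which makes cumulative arrivals pathwise monotone in the
        recruitment rate under a shared seed.
        """
        rate = vasc_mod.recruitment_rate(self.config.rules, self.cumulative_dead_cancer)
        mean = rate * self.dt_h
        u = self._rng_recruit_count.random()
        n_arr = int(poisson.ppf(min(u, 1.0 - 1e-15), mean)) if mean > 0 else 0
        placed = 0
        forfeited = 0
        if n_arr > 0:
            ev = self.vasculature.entry_voxels
            free = np.flatnonzero(self.occ[ev[:, 0], ev[:, 1], ev[:, 2]] < 0)
            take = min(n_arr, free.size)
            if take > 0:
                pick = self._rng_recruit_place.choice(free, size=take, replace=False)
                for j in pick:
                    self.add_agent(T_EFFECTOR, ev[j])
                placed = take
            forfeited = n_arr - placed
        return placed, forfeited

    def secrete_and_diffuse(self) -> None:
        na = self.n_agents
        m = self.alive[:na] & (self.state[:na] == T_CYTOTOXIC)
        if m.any():
            vox = np.stack([self.ax[:na][m], self.ay[:na][m], self.az[:na][m]], axis=1)
            self.field.add_sources(vox, self.dt_h)
        if self.field.grid.max() > 0.0:
            self.field.step(self.dt_h)

    def contact_interactions(self) -> np.ndarray:
        na = self.n_agents
        m = self.alive[:na] & (self.state[:na] >= T_EFFECTOR)
        idx = np.flatnonzero(m)
        counters = np.zeros(5, np.int64)
        if idx.size:
            order = self._rng_abm.permutation(idx)
            u = self._rng_abm.random((idx.size, 4))
            p_supp_eff = treatment_mod.effective_p_supp(
                self.config.rules.p_supp, self.config.treatment, self.t_days
            )
            _kernels.contact_phase(
                order,
                self.state,
                self.ax,
                self.ay,
                self.az,
                self.death_time,
                self.occ,
                u,
                self.config.rules.p_kill_neg,
                self.config.rules.p_kill_pos,
                self.config.rules.p_pdl1_induction,
                p_supp_eff,
                self.config.rules.induction_on_contact,
                self.clock_h,
                counters,
            )
            kills = int(counters[2])
            self.cumulative_kills += kills
            self.cumulative_dead_cancer += kills
        return counters

    def proliferate(self) -> np.ndarray:
        na = self.n_agents
        rules = self.config.rules
        self.cooldown[:na][self.alive[:na]] -= self.dt_h
        st = self.state[:na]
        eligible = (
            self.alive[:na]
            & (st != CANCER_DEAD)
            & (st != T_SUPPRESSED)
            & (self.cooldown[:na] <= 0.0)
        )
        is_t = st >= T_EFFECTOR
        if eligible[is_t].any():
            tm = eligible & is_t
            il2 = self.field.grid[self.ax[:na][tm], self.ay[:na][tm], self.az[:na][tm]]
            ok = (il2 >= rules.il2_division_threshold) & (
                self.divisions[:na][tm] < rules.max_t_cell_divisions
            )
            eligible[np.flatnonzero(tm)] = ok
        cand = np.flatnonzero(eligible)
        counters = np.zeros(3, np.int64)
        if cand.size:
            cand = self._rng_abm.permutation(cand)
            u = self._rng_abm.random(cand.size)
            self._ensure_capacity(cand.size)
            n_new = _kernels.division_phase(
                cand,
                self.state,
                self.ax,
                self.ay,
                self.az,
                self.cooldown,
                self.age,
                self.divisions,
                self.death_time,
                self.alive,
                self.occ,
                u,
                rules.cancer_cycle_time_h,
                rules.t_cell_cycle_time_h,
                rules.division_retry_h,
                self.n_agents,
                counters,
            )
            self.n_agents += int(n_new)
        return counters

    def migrate(self) -> np.ndarray:
        na = self.n_agents
        rules = self.config.rules
        st = self.state[:na]
        motile = self.alive[:na] & (st != CANCER_DEAD)
        counters = np.zeros(2, np.int64)
        idx = np.flatnonzero(motile)
        if idx.size == 0:
            return counters
        speed = np.where(
            st[idx] >= T_EFFECTOR, rules.t_cell_speed_um_min, rules.cancer_speed_um_min
        )
        vox_per_step = speed * 60.0 * self.dt_h / self.voxel_um
        base = np.floor(vox_per_step).astype(np.int64)
        frac = vox_per_step - base
        nmoves = base + (self._rng_abm.random(idx.size) < frac)
        active = nmoves > 0
        idx, nmoves = idx[active], nmoves[active]
        if idx.size == 0:
            return counters
        perm = self._rng_abm.permutation(idx.size)
        order = idx[perm]
        nmoves = nmoves[perm]
        dirs = self._rng_abm.integers(0, 26, size=(idx.size, int(nmoves.max())),
                                      dtype=np.int64)
        _kernels.migration_phase(
            order, self.state, self.ax, self.ay, self.az, self.occ, nmoves, dirs,
            counters,
        )
        return counters

    def deaths_and_clearance(self) -> tuple[int, int, int]:
        na = self.n_agents
        rules = self.config.rules
        t_end = self.clock_h + self.dt_h
        self.age[:na][self.alive[:na]] += self.dt_h
        st = self.state[:na]

        # spontaneous cancer death (turnover / necrosis)
        n_spont = 0
        if rules.spontaneous_death_rate_h > 0:
            living = np.flatnonzero(
                self.alive[:na] & ((st == CANCER_PDL1_NEG) | (st == CANCER_PDL1_POS))
            )
            if living.size:
                p = 1.0 - np.exp(-rules.spontaneous_death_rate_h * self.dt_h)
                hit = living[self._rng_abm.random(living.size) < p]
                self.state[hit] = CANCER_DEAD
                self.death_time[hit] = t_end
                n_spont = hit.size
                self.cumulative_dead_cancer += n_spont

        # T-cell death: lifespan reached or division capacity spent
        tmask = self.alive[:na] & (st >= T_EFFECTOR)
        dying = np.flatnonzero(
            tmask
            & (
                (self.age[:na] >= rules.t_cell_lifespan_h)
                | (self.divisions[:na] >= rules.max_t_cell_divisions)
            )
        )
        for i in dying:
            self.occ[self.ax[i], self.ay[i], self.az[i]] = -1
        self.alive[dying] = False

        # clearance of dead cancer blocks
        cleared = np.flatnonzero(
            self.alive[:na]
            & (st == CANCER_DEAD)
            & (t_end - self.death_time[:na] >= rules.dead_clearance_time_h)
        )
        for i in cleared:
            x, y, z = self.ax[i], self.ay[i], self.az[i]
            self.occ[x : x + 2, y : y + 2, z : z + 2] = -1
        self.alive[cleared] = False
        return n_spont, int(dying.size), int(cleared.size)

    # ------------------------------------------------------------------ #
    # stepping

    def step(self) -> None:
        recruits, forfeited = self.recruit()
        self.secrete_and_diffuse()
        contact = self.contact_interactions()
        div = self.proliferate()
        mig = self.migrate()
        n_spont, t_deaths, cleared = self.deaths_and_clearance()
        self.clock_h += self.dt_h
        self.step_index += 1
        self._event_rows.append(
            [
                self.step_index,
                recruits,
                forfeited,
                int(contact[0]),
                int(contact[1]),
                int(contact[2]),
                int(contact[3]),
                int(contact[4]),
                n_spont,
                int(div[0]),
                int(div[1]),
                int(div[2]),
                t_deaths,
                cleared,
                int(mig[0]),
                int(mig[1]),
            ]
        )
        self._record()

    def _record(self, initial: bool = False) -> None:
        c = self.counts()
        self._ts_rows.append(
            [
                self.step_index,
                self.clock_h,
                self.t_days,
                int(c[CANCER_PDL1_NEG]),
                int(c[CANCER_PDL1_POS]),
                int(c[CANCER_DEAD]),
                int(c[T_EFFECTOR]),
                int(c[T_CYTOTOXIC]),
                int(c[T_SUPPRESSED]),
                self.field.total_mass(),
            ]
        )

    @property
    def time_series(self) -> pd.DataFrame:
        return pd.DataFrame(self._ts_rows, columns=_TS_COLUMNS)

    @property
    def events(self) -> pd.DataFrame:
        return pd.DataFrame(self._event_rows, columns=_EVENT_COLUMNS)

    def clone(self) -> "Simulation":
        """Deep copy (arrays and RNG streams) for coupled paired runs."""
        return copy.deepcopy(self)

    def run(
        self,
        record_days: list[float] | None = None,
        duration_days: float | None = None,
        consistency_checks: bool = False,
    ) -> tuple[pd.DataFrame, dict[float, Snapshot]]:
        """Advance to ``duration_days`` recording snapshots at ``record_days``."""
        duration = (
            self.config.lattice.duration_days if duration_days is None else duration_days
        )
        record_days = sorted(record_days or [])
        if record_days and record_days[-1] > duration + 1e-9:
            raise ConfigurationError("record day beyond simulation duration")
        snaps: dict[float, Snapshot] = {}
        pending = list(record_days)
        if pending and abs(pending[0]) < 1e-9:
            snaps[pending.pop(0)] = self.snapshot()
        n_steps = int(round((duration - self.t_days) * 24.0 / self.dt_h))
        for _ in range(n_steps):
            self.step()
            while pending and self.t_days >= pending[0] - 1e-9:
                d = pending.pop(0)
                snaps[d] = self.snapshot()
                if consistency_checks:
                    self.check_consistency()
        return self.time_series, snaps


def initialize(config: RunConfig, seed: int) -> Simulation:
    """Build a fresh simulation: one PDL1- cancer cell at the lattice centre,
    no T cells, zero cytokine field, clock at zero."""
    return Simulation(config, seed)
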