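"""Engine rules: initialization, contact actions, division, migration,
turnover, bookkeeping and determinism."""

import numpy as np
import pytest

from tmesim import IntegrityError, Simulation, initialize
from tmesim.config import (
    CANCER_DEAD,
    CANCER_PDL1_NEG,
    CANCER_PDL1_POS,
    T_CYTOTOXIC,
    T_EFFECTOR,
    T_SUPPRESSED,
)
from tmesim.errors import ConfigurationError

from conftest import empty_sim, quiet_config


# ---------------------------------------------------------------- init

def test_initialize_places_single_central_cancer_cell():
    sim = initialize(quiet_config(n=100), seed=0)
    assert sim.n_agents == 1
    assert sim.state[0] == CANCER_PDL1_NEG
    assert sim.counts()[CANCER_PDL1_NEG] == 1
    assert sim.field.total_mass() == 0.0
    assert sim.clock_h == 0.0


def test_initialize_centre_block_arithmetic_n8():
    sim = initialize(quiet_config(n=8), seed=0)
    occupied = np.argwhere(sim.occ >= 0)
    assert sorted(map(tuple, occupied)) == [
        (x, y, z) for x in (3, 4) for y in (3, 4) for z in (3, 4)
    ]


def test_initialize_rejects_too_small_lattice():
    cfg = quiet_config(n=8)
    cfg.lattice.n_voxels_per_edge = 4
    with pytest.raises(ConfigurationError):
        initialize(cfg, 0)


def test_identical_seeds_give_identical_occupancy_and_series():
    cfg = quiet_config(
        n=24,
        p_kill_neg=0.3,
        p_supp=0.1,
        cancer_cycle_time_h=24.0,
        t_cell_speed_um_min=1.0,
        r_base=0.3,
        spontaneous_death_rate_h=0.01,
        k_i=0.1,
    )
    sims = []
    for _ in range(2):
        sim = initialize(cfg, seed=42)
        sim.run(duration_days=3.0)
        sims.append(sim)
    assert np.array_equal(sims[0].occ, sims[1].occ)
    assert sims[0].time_series.equals(sims[1].time_series)
    assert sims[0].events.equals(sims[1].events)


# ---------------------------------------------------------------- step basics

def test_step_on_empty_lattice_only_advances_clock():
    sim = empty_sim(n=16)
    occ = sim.occ.copy()
    sim.step()
    assert sim.clock_h == pytest.approx(0.25)
    assert np.array_equal(sim.occ, occ)
    assert sim.n_agents == 0


def test_frozen_dynamics_leave_occupancy_unchanged():
    sim = initialize(quiet_config(n=16), seed=1)
    occ = sim.occ.copy()
    for _ in range(20):
        sim.step()
    assert np.array_equal(sim.occ, occ)


def test_division_with_guaranteed_free_site():
    cfg = quiet_config(n=16, cancer_cycle_time_h=0.25)
    sim = initialize(cfg, seed=2)
    sim.step()
    assert sim.counts()[CANCER_PDL1_NEG] == 2


def test_duration_zero_gives_length_one_series():
    sim = initialize(quiet_config(n=16), seed=0)
    ts, snaps = sim.run(record_days=[0.0], duration_days=0.0)
    assert len(ts) == 1
    assert list(snaps) == [0.0]


# ---------------------------------------------------------------- contacts

def place_pair(sim, t_state=T_CYTOTOXIC, c_state=CANCER_PDL1_NEG):
    c = sim.add_agent(c_state, (6, 6, 6))
    t = sim.add_agent(t_state, (5, 6, 6))
    return t, c


def test_certain_kill_marks_target_dead():
    sim = empty_sim(p_kill_neg=1.0)
    t, c = place_pair(sim)
    sim.contact_interactions()
    assert sim.state[c] == CANCER_DEAD
    assert sim.cumulative_dead_cancer == 1
    assert sim.cumulative_kills == 1


def test_certain_suppression_without_kill():
    sim = empty_sim(p_supp=1.0, p_kill_pos=0.0)
    t, c = place_pair(sim, c_state=CANCER_PDL1_POS)
    sim.contact_interactions()
    assert sim.state[t] == T_SUPPRESSED
    assert sim.state[c] == CANCER_PDL1_POS


def test_effector_activates_deterministically_on_contact():
    sim = empty_sim()
    t, c = place_pair(sim, t_state=T_EFFECTOR)
    sim.contact_interactions()
    assert sim.state[t] == T_CYTOTOXIC
    lone = empty_sim()
    t2 = lone.add_agent(T_EFFECTOR, (3, 3, 3))
    lone.contact_interactions()
    assert lone.state[t2] == T_EFFECTOR  # no cancer contact, no activation


def test_certain_induction_after_failed_attempt():
    sim = empty_sim(p_kill_neg=0.0, p_pdl1_induction=1.0)
    t, c = place_pair(sim)
    sim.contact_interactions()
    assert sim.state[c] == CANCER_PDL1_POS


def test_suppressed_t_cells_never_kill():
    sim = empty_sim(p_kill_neg=1.0, p_kill_pos=1.0)
    t, c = place_pair(sim, t_state=T_SUPPRESSED)
    sim.contact_interactions()
    assert sim.state[c] == CANCER_PDL1_NEG
    ev = sim.events
    assert len(ev) == 0 or ev["kills"].sum() == 0


def test_kill_frequency_matches_binomial_oracle():
    """Monte-Carlo single-contact kill frequency ~ Binomial(n, 0.3)."""
    p = 0.3
    n_trials = 0
    n_kills = 0
    for seed in range(10):
        sim = empty_sim(n=44, seed=seed, p_kill_neg=p)
        for x in range(2, 42, 5):
            for y in range(2, 42, 5):
                for z in (10, 20, 30):
                    sim.add_agent(CANCER_PDL1_NEG, (x, y, z))
                    sim.add_agent(T_CYTOTOXIC, (x - 1, y, z))
        before = sim.counts()[CANCER_PDL1_NEG]
        sim.contact_interactions()
        kills = before - sim.counts()[CANCER_PDL1_NEG]
        n_trials += before
        n_kills += kills
    freq = n_kills / n_trials
    se = np.sqrt(p * (1 - p) / n_trials)
    assert abs(freq - p) <= 3 * se


def test_pdl1_positive_count_non_decreasing_except_death():
    cfg = quiet_config(
        n=24,
        p_kill_neg=0.2,
        p_kill_pos=0.05,
        p_pdl1_induction=0.3,
        p_supp=0.1,
        r_base=0.5,
        k_i=0.1,
        spontaneous_death_rate_h=0.005,
        cancer_cycle_time_h=24.0,
        t_cell_speed_um_min=1.0,
    )
    sim = initialize(cfg, seed=9)
    prev_pos = 0
    for _ in range(200):
        sim.step()
        c = sim.counts()
        ev = sim.events.iloc[-1]
        # PDL1+ can drop only through deaths; inductions and divisions raise it
        assert c[CANCER_PDL1_POS] >= prev_pos - ev["kills"] - ev["spontaneous_deaths"]
        prev_pos = c[CANCER_PDL1_POS]


# ---------------------------------------------------------------- division

def test_t_cell_division_gated_by_il2():
    sim = empty_sim(il2_division_threshold=0.5, t_cell_cycle_time_h=0.25)
    t = sim.add_agent(T_CYTOTOXIC, (8, 8, 8))
    sim.proliferate()
    assert sim.counts()[T_CYTOTOXIC] == 1  # below threshold: no division
    sim.field.grid[8, 8, 8] = 1.0
    sim.cooldown[t] = 0.0
    sim.proliferate()
    assert sim.counts()[T_CYTOTOXIC] == 2


def test_enclosed_cancer_cell_cannot_divide():
    sim = empty_sim(n=12, cancer_cycle_time_h=0.25)
    centre = sim.add_agent(CANCER_PDL1_NEG, (5, 5, 5))
    # wall off the centre block completely with T cells
    for x in range(3, 9):
        for y in range(3, 9):
            for z in range(3, 9):
                if 5 <= x <= 6 and 5 <= y <= 6 and 5 <= z <= 6:
                    continue
                sim.add_agent(T_EFFECTOR, (x, y, z))
    n_before = sim.counts()[CANCER_PDL1_NEG]
    sim.proliferate()
    assert sim.counts()[CANCER_PDL1_NEG] == n_before


def test_unconstrained_growth_matches_exponential_closed_form():
    cfg = quiet_config(n=50, cancer_cycle_time_h=24.0)
    sim = initialize(cfg, seed=5)
    for day in range(1, 9):
        sim.run(duration_days=float(day))
        count = int(sim.counts()[CANCER_PDL1_NEG])
        assert abs(count - 2**day) / 2**day <= 0.10


# ---------------------------------------------------------------- migration

def test_zero_speed_agents_do_not_move():
    sim = empty_sim()
    t = sim.add_agent(T_CYTOTOXIC, (4, 4, 4))
    for _ in range(10):
        sim.migrate()
    assert (sim.ax[t], sim.ay[t], sim.az[t]) == (4, 4, 4)


def test_unit_speed_lone_walker_moves_every_step():
    # speed voxel/dt: 10 um / 0.25 h = 40 um/h = 2/3 um/min
    sim = empty_sim(n=30, t_cell_speed_um_min=10.0 / 15.0)
    t = sim.add_agent(T_CYTOTOXIC, (15, 15, 15))
    for _ in range(30):
        before = (sim.ax[t], sim.ay[t], sim.az[t])
        sim.migrate()
        after = (sim.ax[t], sim.ay[t], sim.az[t])
        assert after != before
        assert max(abs(a - b) for a, b in zip(after, before)) == 1


def test_random_walk_msd_linear_in_time():
    sim = empty_sim(n=60, seed=3, t_cell_speed_um_min=10.0 / 15.0)
    t = sim.add_agent(T_CYTOTOXIC, (30, 30, 30))
    pos = []
    for _ in range(2000):
        sim.migrate()
        pos.append((sim.ax[t], sim.ay[t], sim.az[t]))
    pos = np.array(pos, float)
    taus = np.arange(5, 105, 5)
    msd = [
        np.mean(np.sum((pos[tau:] - pos[:-tau]) ** 2, axis=1)) for tau in taus
    ]
    slope, intercept = np.polyfit(taus, msd, 1)
    pred = slope * taus + intercept
    ss_res = np.sum((msd - pred) ** 2)
    ss_tot = np.sum((msd - np.mean(msd)) ** 2)
    assert 1 - ss_res / ss_tot > 0.95
    assert slope > 0


# ---------------------------------------------------------------- turnover

def test_dead_cancer_blocks_persist_then_clear():
    sim = empty_sim(p_kill_neg=1.0, dead_clearance_time_h=1.0)
    t, c = place_pair(sim)
    sim.contact_interactions()
    assert sim.state[c] == CANCER_DEAD
    sim.deaths_and_clearance()
    assert sim.alive[c]  # still occupying its block
    for _ in range(4):
        sim.clock_h += 0.25
        sim.deaths_and_clearance()
    assert not sim.alive[c]
    assert (sim.occ[6:8, 6:8, 6:8] == -1).all()


def test_t_cells_die_at_lifespan():
    sim = empty_sim(t_cell_lifespan_h=1.0)
    t = sim.add_agent(T_EFFECTOR, (4, 4, 4))
    for _ in range(4):
        sim.step()
    assert not sim.alive[t]
    assert sim.occ[4, 4, 4] == -1


# ---------------------------------------------------------------- audits

def test_conservation_and_consistency_on_stochastic_run():
    cfg = quiet_config(
        n=30,
        p_kill_neg=0.3,
        p_kill_pos=0.1,
        p_supp=0.1,
        p_pdl1_induction=0.1,
        r_base=0.4,
        k_i=0.1,
        spontaneous_death_rate_h=0.005,
        cancer_cycle_time_h=24.0,
        t_cell_speed_um_min=1.0,
        t_cell_cycle_time_h=12.0,
        il2_division_threshold=0.0,
        dead_clearance_time_h=24.0,
        t_cell_lifespan_h=96.0,
    )
    cfg.cytokine.secretion_rate_h = 1.0
    sim = initialize(cfg, seed=11)
    sim.run(duration_days=6.0)
    sim.check_consistency()
    ts, ev = sim.time_series, sim.events
    living = ts["cancer_pdl1_neg"] + ts["cancer_pdl1_pos"]
    deltas = living.diff().dropna().to_numpy()
    expected = (
        ev["cancer_divisions"] - ev["kills"] - ev["spontaneous_deaths"]
    ).to_numpy()
    assert np.array_equal(deltas, expected)
    assert sim.cumulative_dead_cancer == ev["kills"].sum() + ev["spontaneous_deaths"].sum()
    assert (ts[["cancer_pdl1_neg", "cancer_pdl1_pos", "cancer_dead",
                "t_effector", "t_cytotoxic", "t_suppressed"]] >= 0).all().all()


def test_corrupted_occupancy_raises_integrity_error():
    sim = initialize(quiet_config(n=16), seed=0)
    sim.occ[0, 0, 0] = 0  # stale duplicate entry
    with pytest.raises(IntegrityError):
        sim.check_consistency()


def test_add_agent_rejects_collisions_and_out_of_bounds():
    sim = empty_sim(n=10)
    sim.add_agent(CANCER_PDL1_NEG, (4, 4, 4))
    with pytest.raises(IntegrityError):
        sim.add_agent(T_EFFECTOR, (5, 5, 5))
    with pytest.raises(ConfigurationError):
        sim.add_agent(CANCER_PDL1_NEG, (9, 9, 9))  # block would leave lattice


def test_contact_conditioned_induction_switch():
    """With induction_on_contact, conversion does not require a kill attempt:
    even a suppressed T cell in contact can induce PDL1."""
    sim = empty_sim(p_pdl1_induction=1.0)
    sim.config.rules.induction_on_contact = True
    t, c = place_pair(sim, t_state=T_SUPPRESSED)
    sim.contact_interactions()
    assert sim.state[c] == CANCER_PDL1_POS
    # default (failed-attempt-conditioned): a suppressed T cell cannot induce
    sim2 = empty_sim(p_pdl1_induction=1.0)
    t2, c2 = place_pair(sim2, t_state=T_SUPPRESSED)
    sim2.contact_interactions()
    assert sim2.state[c2] == CANCER_PDL1_NEG
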