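"""Run configuration: lattice geometry, agent rule parameters, cytokine
parameters and the treatment schedule.

All per-event probabilities are *per contact step* (one ABM time step of
``dt_hours``); rates carry explicit units in their field names.  The model is
deliberately phenomenological — none of these values is calibrated to a
specific cancer type — so every rate and probability is exposed here with a
documented default.  The shipped defaults reproduce the qualitative baseline
sequence (T-cell arrival around day 10, slowdown of cancer growth, emergence
of PDL1+ cancer cells) for the high-burden/high-strength neoantigen profile
(k_a = 20, k_i = 0.1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

SCHEMA_VERSION = 1

# Frozen state -> code table used in label volumes and snapshots.
EMPTY = 0
CANCER_PDL1_NEG = 1
CANCER_PDL1_POS = 2
CANCER_DEAD = 3
T_EFFECTOR = 4
T_CYTOTOXIC = 5
T_SUPPRESSED = 6

CANCER_STATES = (CANCER_PDL1_NEG, CANCER_PDL1_POS, CANCER_DEAD)
LIVING_CANCER_STATES = (CANCER_PDL1_NEG, CANCER_PDL1_POS)
T_CELL_STATES = (T_EFFECTOR, T_CYTOTOXIC, T_SUPPRESSED)

STATE_NAMES = {
    EMPTY: "empty",
    CANCER_PDL1_NEG: "cancer_pdl1_neg",
    CANCER_PDL1_POS: "cancer_pdl1_pos",
    CANCER_DEAD: "cancer_dead",
    T_EFFECTOR: "t_effector",
    T_CYTOTOXIC: "t_cytotoxic",
    T_SUPPRESSED: "t_suppressed",
}

T_CELL_EDGE_VOXELS = 1   # T cells are ~10 um, one voxel
CANCER_EDGE_VOXELS = 2   # cancer cells are ~20 um, an aligned 2x2x2 block


@dataclass
class LatticeConfig:
    """Simulation domain: a cubic lattice of ``n_voxels_per_edge``^3 voxels.

    The default 100-voxel edge at 10 um per voxel is a 1 mm^3 domain
    (1 million voxels); scaled-down runs shrink the edge, not the voxel.
    """

    n_voxels_per_edge: int = 100
    voxel_size_um: float = 10.0
    duration_days: float = 50.0
    dt_hours: float = 0.25

    def validate(self) -> None:
        if self.n_voxels_per_edge < 8:
            raise ConfigurationError(
                f"lattice edge must be >= 8 voxels, got {self.n_voxels_per_edge}"
            )
        if self.voxel_size_um <= 0:
            raise ConfigurationError("voxel_size_um must be positive")
        if self.dt_hours <= 0:
            raise ConfigurationError("dt_hours must be positive")
        if self.duration_days < 0:
            raise ConfigurationError("duration_days must be non-negative")


@dataclass
class RuleParameters:
    """Per-event probabilities and rates for the cellular agents.

    Kill/suppression/induction probabilities are per contact step; speeds are
    um per minute; cycle, lifespan and clearance times are hours.  ``k_a``
    (mutational burden) and ``k_i`` (antigen strength) parameterize the
    neoantigen profile and enter only through the effector recruitment rate.
    """

    # T-cell offensive actions
    p_kill_neg: float = 0.15        # kill prob vs a PDL1- target per step
    p_kill_pos: float = 0.10        # reduced kill prob vs a PDL1+ target
    p_pdl1_induction: float = 0.2   # PDL1- -> PDL1+ after surviving an attempt
    p_supp: float = 0.08            # cytotoxic -> suppressed per step near PDL1+
    induction_on_contact: bool = False  # if True, induction needs contact only

    # proliferation
    il2_division_threshold: float = 0.012  # local IL-2 (arb. units) gating T division
    cancer_cycle_time_h: float = 36.0
    t_cell_cycle_time_h: float = 8.0
    max_t_cell_divisions: int = 8
    division_retry_h: float = 1.0  # re-attempt interval after a blocked division

    # motility (um / min)
    t_cell_speed_um_min: float = 1.0
    cancer_speed_um_min: float = 0.02

    # turnover
    t_cell_lifespan_h: float = 168.0       # 7 days
    dead_clearance_time_h: float = 24.0
    spontaneous_death_rate_h: float = 0.001  # cancer necrosis hazard, h^-1

    # neoantigen profile and recruitment
    k_a: float = 20.0     # mutational burden (dimensionless)
    k_i: float = 0.1      # antigen strength (dimensionless)
    r_base: float = 0.08  # recruitment scale, arrivals h^-1 per unit k_a

    # vasculature
    lambda_vasc_per_um: float = 0.01   # decay of entry density with depth
    base_entry_density: float = 0.02   # entry-point probability at depth 0

    def validate(self) -> None:
        for name in (
            "p_kill_neg",
            "p_kill_pos",
            "p_pdl1_induction",
            "p_supp",
            "base_entry_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.p_kill_pos > self.p_kill_neg:
            raise ConfigurationError("p_kill_pos must not exceed p_kill_neg")
        for name in (
            "t_cell_speed_um_min",
            "cancer_speed_um_min",
            "spontaneous_death_rate_h",
            "r_base",
            "lambda_vasc_per_um",
            "il2_division_threshold",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("k_a", "k_i"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.division_retry_h <= 0:
            raise ConfigurationError("division_retry_h must be positive")
        for name in ("cancer_cycle_time_h", "t_cell_cycle_time_h",
                     "t_cell_lifespan_h", "dead_clearance_time_h"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_t_cell_divisions < 0:
            raise ConfigurationError("max_t_cell_divisions must be >= 0")


@dataclass
class CytokineParameters:
    """IL-2 field parameters (secretion by cytotoxic T cells, diffusion, decay)."""

    diffusion_um2_s: float = 10.0
    decay_rate_h: float = 0.693       # half-life ~1 h
    secretion_rate_h: float = 1.0     # units h^-1 per secreting cell
    substeps_per_dt: int = 10         # PDE substeps within one ABM step

    def validate(self) -> None:
        if self.diffusion_um2_s < 0 or self.decay_rate_h < 0 or self.secretion_rate_h < 0:
            raise ConfigurationError("cytokine parameters must be non-negative")
        if self.substeps_per_dt < 1:
            raise ConfigurationError("substeps_per_dt must be >= 1")


@dataclass
class TreatmentSchedule:
    """Anti-PDL1 checkpoint blockade: from ``start_day`` on, the suppression
    probability is rescaled to p_supp * (1 - m_supp). Incomplete blocking
    (m_supp < 1) stands in for redundant ligands such as PDL2."""

    enabled: bool = False
    start_day: float = 30.0
    m_supp: float = 0.8

    def validate(self) -> None:
        if not 0.0 <= self.m_supp <= 1.0:
            raise ConfigurationError(f"m_supp must be in [0,1], got {self.m_supp}")
        if self.start_day < 0:
            raise ConfigurationError("start_day must be >= 0")


@dataclass
class RunConfig:
    """Complete configuration for one simulation run."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    rules: RuleParameters = field(default_factory=RuleParameters)
    cytokine: CytokineParameters = field(default_factory=CytokineParameters)
    treatment: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"config schema version {self.schema_version} not supported "
                f"(expected {SCHEMA_VERSION})"
            )
        self.lattice.validate()
        self.rules.validate()
        self.cytokine.validate()
        self.treatment.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            cfg = cls(
                lattice=LatticeConfig(**d.get("lattice", {})),
                rules=RuleParameters(**d.get("rules", {})),
                cytokine=CytokineParameters(**d.get("cytokine", {})),
                treatment=TreatmentSchedule(**d.get("treatment", {})),
                schema_version=d.get("schema_version", SCHEMA_VERSION),
            )
        except TypeError as exc:  # unknown key
            raise ConfigurationError(f"invalid configuration: {exc}") from exc
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Stable hash of the full configuration, embedded in run artefacts."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig()


def save_config(config: RunConfig, path: str | Path) -> None:
    config.validate()
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)
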