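import numpy as np
import pytest

from tmesim import RunConfig, Simulation


def quiet_config(n=20, dt_h=0.25, **rules) -> RunConfig:
    """Config with every stochastic channel switched off; individual tests
    re-enable exactly the rule under study."""
    cfg = RunConfig()
    cfg.lattice.n_voxels_per_edge = n
    cfg.lattice.duration_days = 5.0
    cfg.lattice.dt_hours = dt_h
    r = cfg.rules
    r.p_kill_neg = 0.0
    r.p_kill_pos = 0.0
    r.p_pdl1_induction = 0.0
    r.p_supp = 0.0
    r.t_cell_speed_um_min = 0.0
    r.cancer_speed_um_min = 0.0
    r.cancer_cycle_time_h = 1e9
    r.t_cell_cycle_time_h = 1e9
    r.t_cell_lifespan_h = 1e9
    r.dead_clearance_time_h = 1e9
    r.spontaneous_death_rate_h = 0.0
    r.r_base = 0.0
    r.il2_division_threshold = 0.0
    cfg.cytokine.secretion_rate_h = 0.0
    for name, value in rules.items():
        setattr(r, name, value)
    cfg.validate()
    return cfg


def empty_sim(n=20, seed=0, dt_h=0.25, **rules) -> Simulation:
    return Simulation(quiet_config(n=n, dt_h=dt_h, **rules), seed, seed_tumor=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
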