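"""Simulated anti-PDL1 checkpoint blockade.

The drug is represented purely through the suppression channel: from
``start_day`` onward the per-contact-step probability of a cytotoxic T cell
being suppressed by a PDL1+ cancer cell is rescaled to

    p' = p_supp * (1 - m_supp)

so m_supp = 0.8 is an 80% reduction, and m_supp < 1 encodes incomplete
blocking (redundant ligands such as PDL2).  Kill probabilities against PDL1+
cells are unaffected.
"""

from __future__ import annotations

from .config import TreatmentSchedule


def effective_p_supp(p_supp: float, schedule: TreatmentSchedule, t_days: float) -> float:
    """Suppression probability in force at simulated time ``t_days``."""
    if not 0.0 <= p_supp <= 1.0:
        raise ValueError(f"p_supp must be in [0,1], got {p_supp}")
    if not schedule.enabled or t_days < schedule.start_day:
        return p_supp
    return p_supp * (1.0 - schedule.m_supp)
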