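"""Rim-PDL1 biomarker scoring and ROC evaluation over virtual cohorts.

The rim score of a tumour cross section is the fraction of living cancer
cells, within a fixed depth of the tumour surface, that are PDL1+.  Treatment
outcome is summarized by the shrinkage ratio (total living cancer at the
post-treatment day over the pre-treatment day; 1 equilibrium, 0 elimination,
>1 progression) and a responder flag.  The predictive value of the score is
assessed with empirical ROC curves across rim-depth thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .config import CANCER_PDL1_NEG, CANCER_PDL1_POS
from .spatial import CrossSectionAnalysis, cross_sections, rim_mask, tumor_mask_from_labels

DEFAULT_RIM_THRESHOLDS_UM = (20.0, 50.0, 100.0, 150.0)


@dataclass
class RimScore:
    threshold_um: float
    per_section_scores: list[float]   # NaN where the rim holds no cancer cell
    score: float                      # mean over defined sections; NaN if none

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


@dataclass
class ResponseLabel:
    shrinkage_ratio: float
    responder: bool


def rim_pdl1_score_section(
    section: CrossSectionAnalysis,
    rim: np.ndarray,
    count_agents: bool = True,
) -> float:
    """PDL1+ fraction among living cancer cells in the rim of one section.

    With ``count_agents`` (default) a multi-voxel cancer cell whose block
    intersects the rim counts once, which needs the section's agent-id table;
    otherwise counting is voxel-weighted.  NaN when the rim holds no living
    cancer cell.
    """
    labels = section.cell_table
    in_rim = np.asarray(rim, bool)
    if count_agents and section.id_table is not None:
        sel = in_rim & np.isin(labels, (CANCER_PDL1_NEG, CANCER_PDL1_POS))
        if not sel.any():
            return float("nan")
        ids = section.id_table[sel]
        states = labels[sel]
        uniq, first = np.unique(ids, return_index=True)
        states = states[first]
        return float((states == CANCER_PDL1_POS).sum() / states.size)
    n_pos = int((in_rim & (labels == CANCER_PDL1_POS)).sum())
    n_liv = n_pos + int((in_rim & (labels == CANCER_PDL1_NEG)).sum())
    if n_liv == 0:
        return float("nan")
    return n_pos / n_liv


def rim_pdl1_score(
    sections: list[CrossSectionAnalysis],
    threshold_um: float,
    count_agents: bool = True,
) -> RimScore:
    """Rim score per section plus the mean over sections with a defined score."""
    per = []
    for s in sections:
        rim = rim_mask(s.distance_map, threshold_um)
        per.append(rim_pdl1_score_section(s, rim, count_agents=count_agents))
    defined = [v for v in per if not math.isnan(v)]
    agg = float(np.mean(defined)) if defined else float("nan")
    return RimScore(threshold_um=threshold_um, per_section_scores=per, score=agg)


def score_snapshot(
    labels: np.ndarray,
    threshold_um: float,
    voxel_size_um: float = 10.0,
    ids: np.ndarray | None = None,
    include_dead: bool = True,
) -> RimScore:
    """Convenience path: label volume -> tumour region -> sections -> score."""
    mask = tumor_mask_from_labels(labels, include_dead=include_dead)
    secs = cross_sections(mask.tumor_region, labels, voxel_size_um, ids=ids)
    return rim_pdl1_score(secs, threshold_um)


def shrinkage_ratio(
    time_series: pd.DataFrame,
    pre_day: float,
    post_day: float,
    responder_cutoff: float = 1.0,
) -> ResponseLabel:
    """Post/pre ratio of total living cancer counts from a run time series."""

    def _count(day: float) -> int:
        i = (time_series["time_d"] - day).abs().idxmin()
        row = time_series.loc[i]
        if abs(row["time_d"] - day) > 0.51:
            raise ValueError(f"day {day} not recorded in the time series")
        return int(row["cancer_pdl1_neg"] + row["cancer_pdl1_pos"])

    pre = _count(pre_day)
    post = _count(post_day)
    if pre == 0:
        raise ValueError("pre-treatment cancer count is zero; ratio undefined")
    ratio = post / pre
    return ResponseLabel(shrinkage_ratio=ratio, responder=ratio < responder_cutoff)


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC (ties grouped) and trapezoidal AUC.

    ``labels`` are responder flags; higher scores are taken to indicate
    responders.  Raises on single-class labels or undefined scores.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and equal length")
    if np.isnan(scores).any():
        raise ValueError("scores contain undefined (NaN) values; exclude them first")
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one responder and one non-responder")
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def threshold_sweep(
    cohort: pd.DataFrame,
    thresholds_um=DEFAULT_RIM_THRESHOLDS_UM,
) -> dict[float, dict]:
    """One ROC per rim threshold on a cohort table.

    ``cohort`` must hold one row per virtual patient with a boolean
    ``responder`` column and a ``score_<threshold>`` column per threshold
    (as produced by :func:`tmesim.scenarios.build_cohort_table`).  Patients
    with an undefined score at a threshold are excluded from that ROC.
    """
    out: dict[float, dict] = {}
    for thr in thresholds_um:
        if thr <= 0:
            raise ValueError("rim thresholds must be positive")
        col = score_column(thr)
        sub = cohort.dropna(subset=[col])
        fpr, tpr, a = roc_curve(sub[col].to_numpy(), sub["responder"].to_numpy())
        out[thr] = {
            "fpr": fpr,
            "tpr": tpr,
            "auc": a,
            "n": int(len(sub)),
            "excluded": int(len(cohort) - len(sub)),
        }
    return out


def score_column(threshold_um: float) -> str:
    v = f"{threshold_um:g}"
    return f"score_{v}"
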