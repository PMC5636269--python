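"""Tumour spatial characterization.

Pipeline: binarize occupancy into L_raw (1 where a voxel holds a cancer cell
of any state), smooth with an unweighted 3x3x3 moving average over the
zero-padded lattice thresholded at 0.5 to get L_smooth, define the tumour
region as the complement of the background (the L_smooth = 0 set reachable
from the lattice faces through 6-connected zero voxels, so sealed cavities
count as tumour), then take the three central cross sections and compute
per-section Euclidean distance maps to the tumour surface.

Distances are centre-to-centre: for each in-tumour pixel, the Euclidean
distance (um) to the nearest out-of-tumour pixel centre within the section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import CANCER_DEAD, CANCER_PDL1_NEG, CANCER_PDL1_POS


@dataclass
class TumorMask:
    l_raw: np.ndarray
    l_smooth: np.ndarray
    tumor_region: np.ndarray


@dataclass
class CrossSectionAnalysis:
    """One central cross section: tumour mask, distance map and cell labels."""

    axis: str                 # "x", "y" or "z"
    index: int                # floor(N/2)
    section_mask: np.ndarray  # 2D bool tumour mask
    distance_map: np.ndarray  # um; NaN outside the tumour
    cell_table: np.ndarray    # 2D uint8 state codes
    id_table: np.ndarray | None = None  # 2D agent ids, -1 empty
    voxel_size_um: float = 10.0


def export_section_csv(section: "CrossSectionAnalysis", path) -> None:
    """Write a section's cell-state label matrix as CSV."""
    np.savetxt(path, section.cell_table, fmt="%d", delimiter=",")


def export_section_png(section: "CrossSectionAnalysis", path) -> None:
    """Write a colour-coded PNG preview of a section's cell states."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colors, pyplot as plt

    cmap = colors.ListedColormap(
        ["white", "#7fc97f", "#2c944c", "#8c8c8c", "#fdc086", "#d95f02", "#7570b3"]
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(section.cell_table, cmap=cmap, vmin=0, vmax=6,
              interpolation="nearest")
    ax.set_title(f"section {section.axis} = {section.index}")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _check_binary(vol: np.ndarray, name: str) -> np.ndarray:
    vol = np.asarray(vol)
    if not np.isin(vol, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return vol.astype(np.uint8)


def raw_labels(cell_labels: np.ndarray, include_dead: bool = True) -> np.ndarray:
    """L_raw from a state-code volume: 1 where a cancer cell sits."""
    states = [CANCER_PDL1_NEG, CANCER_PDL1_POS] + ([CANCER_DEAD] if include_dead else [])
    return np.isin(cell_labels, states).astype(np.uint8)


def smooth_labels(l_raw: np.ndarray) -> np.ndarray:
    """3x3x3 unweighted moving average over the zero-padded volume, >= 0.5.

    Computed as integer box sums so the threshold comparison is exact
    (box mean >= 0.5 iff box sum >= 14; a sum of 13.5 is unattainable).
    """
    l_raw = _check_binary(l_raw, "l_raw")
    sums = ndimage.correlate(
        l_raw.astype(np.int32), np.ones((3, 3, 3), np.int32), mode="constant", cval=0
    )
    return (2 * sums >= 27).astype(np.uint8)


def tumor_region(l_smooth: np.ndarray) -> np.ndarray:
    """Complement of the face-connected L_smooth=0 background (6-connected)."""
    l_smooth = _check_binary(l_smooth, "l_smooth")
    zero = l_smooth == 0
    structure = ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(zero, structure=structure)
    face_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    face_labels = face_labels[face_labels > 0]
    background = np.isin(labels, face_labels)
    return (~background).astype(np.uint8)


def tumor_mask_from_labels(cell_labels: np.ndarray, include_dead: bool = True) -> TumorMask:
    l_raw = raw_labels(cell_labels, include_dead=include_dead)
    l_smooth = smooth_labels(l_raw)
    return TumorMask(l_raw=l_raw, l_smooth=l_smooth, tumor_region=tumor_region(l_smooth))


def distance_map(section_mask: np.ndarray, voxel_size_um: float = 10.0) -> np.ndarray:
    """Per-pixel Euclidean distance (um) to the nearest out-of-tumour pixel
    centre; NaN outside the mask.  A mask without background yields +inf."""
    mask = np.asarray(section_mask).astype(bool)
    out = np.full(mask.shape, np.nan)
    if not mask.any():
        return out
    if mask.all():
        out[mask] = np.inf
        return out
    d = ndimage.distance_transform_edt(mask) * voxel_size_um
    out[mask] = d[mask]
    return out


def rim_mask(dist: np.ndarray, threshold_um: float) -> np.ndarray:
    """In-tumour pixels within ``threshold_um`` of the tumour surface.

    With the centre-to-centre convention the smallest in-tumour distance is
    one voxel, so thresholds below the voxel size select nothing; rims nest
    monotonically in the threshold.
    """
    if threshold_um < 0:
        raise ValueError("threshold_um must be >= 0")
    return np.asarray(np.nan_to_num(dist, nan=np.inf, posinf=np.inf) <= threshold_um)


def cross_sections(
    region: np.ndarray,
    cell_labels: np.ndarray,
    voxel_size_um: float = 10.0,
    ids: np.ndarray | None = None,
) -> list[CrossSectionAnalysis]:
    """The three central sections (planes through floor(N/2) per axis)."""
    region = np.asarray(region).astype(bool)
    n = region.shape[0]
    c = n // 2
    out = []
    for axis_name, axis in (("x", 0), ("y", 1), ("z", 2)):
        mask2d = np.take(region, c, axis=axis)
        labels2d = np.take(cell_labels, c, axis=axis)
        ids2d = np.take(ids, c, axis=axis) if ids is not None else None
        out.append(
            CrossSectionAnalysis(
                axis=axis_name,
                index=c,
                section_mask=mask2d,
                distance_map=distance_map(mask2d, voxel_size_um),
                cell_table=labels2d,
                id_table=ids2d,
                voxel_size_um=voxel_size_um,
            )
        )
    return out
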