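"""Spatial-analysis pipeline against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from tmesim import (
    cross_sections,
    distance_map,
    make_fixture,
    rim_mask,
    smooth_labels,
    tumor_region,
)
from tmesim.config import CANCER_PDL1_NEG, CANCER_PDL1_POS
from tmesim.spatial import raw_labels, tumor_mask_from_labels


# ---------------------------------------------------------------- oracles

def smooth_oracle(vol):
    """Direct triple-sum evaluation of the zero-padded 3x3x3 box mean."""
    n0, n1, n2 = vol.shape
    out = np.zeros_like(vol, dtype=np.uint8)
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                s = 0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if 0 <= ii < n0 and 0 <= jj < n1 and 0 <= kk < n2:
                                s += vol[ii, jj, kk]
                out[i, j, k] = 1 if s / 27.0 >= 0.5 else 0
    return out


def flood_oracle(vol):
    """BFS flood fill of zeros from the faces (6-connected); complement."""
    from collections import deque

    n0, n1, n2 = vol.shape
    bg = np.zeros(vol.shape, bool)
    q = deque()
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                if (i in (0, n0 - 1) or j in (0, n1 - 1) or k in (0, n2 - 1)) and vol[
                    i, j, k
                ] == 0:
                    if not bg[i, j, k]:
                        bg[i, j, k] = True
                        q.append((i, j, k))
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if 0 <= ii < n0 and 0 <= jj < n1 and 0 <= kk < n2:
                if vol[ii, jj, kk] == 0 and not bg[ii, jj, kk]:
                    bg[ii, jj, kk] = True
                    q.append((ii, jj, kk))
    return (~bg).astype(np.uint8)


def distance_oracle(mask, voxel=10.0):
    """All-pairs scan: nearest background pixel centre per in-mask pixel."""
    mask = mask.astype(bool)
    out = np.full(mask.shape, np.nan)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if fg.size == 0:
        return out
    if bg.size == 0:
        out[mask] = np.inf
        return out
    d = cdist(fg, bg).min(axis=1) * voxel
    out[tuple(fg.T)] = d
    return out


# ---------------------------------------------------------------- smoothing

def test_smoothing_examples():
    # isolated voxel vanishes: best box mean is 1/27 < 0.5
    vol = np.zeros((9, 9, 9), np.uint8)
    vol[4, 4, 4] = 1
    assert smooth_labels(vol).sum() == 0
    # all-ones volume: interior preserved; the zero-padded box mean erodes
    # lattice edge/corner voxels (box sums 12 and 8 fall below 13.5)
    ones = np.ones((6, 6, 6), np.uint8)
    sm = smooth_labels(ones)
    assert sm[1:-1, 1:-1, 1:-1].all()
    assert sm[0, 1:-1, 1:-1].all()       # face voxels keep box sum 18
    assert sm[0, 0, 0] == 0
    # solid 3x3x3 cube: centre box sum 27 -> kept; corner box sum 8 -> dropped
    vol = np.zeros((9, 9, 9), np.uint8)
    vol[3:6, 3:6, 3:6] = 1
    sm = smooth_labels(vol)
    assert sm[4, 4, 4] == 1
    assert sm[3, 3, 3] == 0


def test_smoothing_rejects_non_binary():
    with pytest.raises(ValueError):
        smooth_labels(np.full((4, 4, 4), 2))


def test_smoothing_matches_triple_sum_oracle_on_random_volumes(rng):
    for _ in range(20):
        vol = (rng.random((16, 16, 16)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        assert np.array_equal(smooth_labels(vol), smooth_oracle(vol))


# ---------------------------------------------------------------- tumour region

def test_tumor_region_trivial_cases():
    assert tumor_region(np.zeros((8, 8, 8), np.uint8)).sum() == 0
    cube = make_fixture("solid_cube", {"n": 20, "edge": 8})
    assert np.array_equal(tumor_region(cube), cube)


def test_sealed_cavity_counts_as_tumour():
    shell = make_fixture("hollow_shell", {"n": 20, "outer": 12, "thickness": 3})
    region = tumor_region(shell)
    assert np.array_equal(region, flood_oracle(shell))
    interior = shell.copy()
    lo = (20 - 12) // 2 + 3
    hi = (20 - 12) // 2 + 12 - 3
    assert region[lo:hi, lo:hi, lo:hi].all()          # cavity included
    assert region.sum() > shell.sum()


def test_tumor_region_matches_flood_fill_oracle_on_random_volumes(rng):
    for _ in range(20):
        vol = (rng.random((16, 16, 16)) < rng.uniform(0.3, 0.7)).astype(np.uint8)
        assert np.array_equal(tumor_region(vol), flood_oracle(vol))


# ---------------------------------------------------------------- sections

def test_cross_sections_indices_and_symmetry():
    n = 100
    region = np.zeros((n, n, n), np.uint8)
    region[40:60, 40:60, 40:60] = 1
    labels = region.copy()
    secs = cross_sections(region, labels)
    assert [s.index for s in secs] == [50, 50, 50]
    assert [s.axis for s in secs] == ["x", "y", "z"]
    for s in secs[1:]:
        assert np.array_equal(s.section_mask, secs[0].section_mask)
    n7 = np.zeros((7, 7, 7), np.uint8)
    assert cross_sections(n7, n7)[0].index == 3


# ---------------------------------------------------------------- distances

def test_single_pixel_tumour_distance_is_one_voxel():
    mask = np.zeros((9, 9), np.uint8)
    mask[4, 4] = 1
    d = distance_map(mask, voxel_size_um=10.0)
    assert d[4, 4] == pytest.approx(10.0)
    assert np.isnan(d[0, 0])


def test_disc_max_distance_close_to_radius():
    disc = make_fixture("digital_disc_section", {"n": 48, "radius_px": 15})
    d = distance_map(disc, voxel_size_um=10.0)
    assert abs(np.nanmax(d) - 150.0) <= 10.0


def test_empty_mask_gives_empty_map():
    d = distance_map(np.zeros((5, 5), np.uint8))
    assert np.isnan(d).all()


def test_distance_matches_brute_force_oracle_on_random_sections(rng):
    for _ in range(10):
        mask = (rng.random((48, 48)) < 0.5).astype(np.uint8)
        got = distance_map(mask, 10.0)
        want = distance_oracle(mask, 10.0)
        assert np.allclose(
            np.nan_to_num(got, nan=-1), np.nan_to_num(want, nan=-1), atol=1e-9
        )


# ---------------------------------------------------------------- rim

def test_rim_annulus_pixel_exact_against_oracle():
    disc = make_fixture("digital_disc_section", {"n": 48, "radius_px": 20})
    d = distance_map(disc, 10.0)
    rim = rim_mask(d, 50.0)
    want = distance_oracle(disc, 10.0)
    assert np.array_equal(rim, np.nan_to_num(want, nan=np.inf) <= 50.0)
    assert rim.sum() > 0
    assert not rim[24, 24]  # disc centre is deeper than 50 um


def test_rim_tiny_threshold_selects_boundary_adjacent_pixels():
    disc = make_fixture("digital_disc_section", {"n": 32, "radius_px": 10})
    d = distance_map(disc, 10.0)
    rim = rim_mask(d, 10.0)
    # exactly the in-disc pixels with a background pixel among their neighbours
    from scipy import ndimage

    # pixels at centre distance exactly one voxel are those with an
    # orthogonally adjacent background pixel (diagonal-only gives sqrt(2))
    boundary = disc.astype(bool) & ~ndimage.binary_erosion(
        disc.astype(bool), structure=ndimage.generate_binary_structure(2, 1),
        border_value=1,
    )
    assert np.array_equal(rim, boundary)


def test_rim_covers_whole_tumour_at_large_threshold_and_nests():
    disc = make_fixture("digital_disc_section", {"n": 48, "radius_px": 15})
    d = distance_map(disc, 10.0)
    assert np.array_equal(rim_mask(d, 1e9), disc.astype(bool))
    prev = rim_mask(d, 0.0)
    for thr in (10.0, 30.0, 60.0, 90.0, 200.0):
        cur = rim_mask(d, thr)
        assert (prev <= cur).all()
        prev = cur


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_rim_nesting_property_on_random_masks(seed):
    mask = make_fixture("random_binary", {"n": 24, "ndim": 2, "p": 0.6}, seed=seed)
    d = distance_map(mask, 10.0)
    small, large = rim_mask(d, 20.0), rim_mask(d, 70.0)
    assert (small <= large).all()
    assert (large <= mask.astype(bool)).all()


# ---------------------------------------------------------------- end to end

def test_raw_labels_include_dead_by_default_with_switch():
    labels = np.zeros((8, 8, 8), np.uint8)
    labels[1, 1, 1] = CANCER_PDL1_NEG
    labels[2, 2, 2] = 3  # dead cancer
    labels[3, 3, 3] = 5  # cytotoxic T cell
    assert raw_labels(labels).sum() == 2
    assert raw_labels(labels, include_dead=False).sum() == 1


def test_pipeline_on_solid_tumour_phantom():
    n = 40
    labels = np.zeros((n, n, n), np.uint8)
    labels[12:28, 12:28, 12:28] = CANCER_PDL1_NEG
    labels[12:28, 12:28, 12:14] = CANCER_PDL1_POS
    tm = tumor_mask_from_labels(labels)
    # smoothing drops the cube's 3D edge/corner voxels (12*14 + 8 = 176)
    assert tm.tumor_region.sum() == 16**3 - 176
    assert np.array_equal(tm.tumor_region, tm.l_smooth)  # no cavities
    secs = cross_sections(tm.tumor_region, labels)
    for s in secs:
        # central plane: square minus the four in-plane corners (3D edges)
        assert s.section_mask.sum() == 16**2 - 4
        inside = s.distance_map[s.section_mask]
        assert np.nanmin(inside) >= 10.0
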