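"""Deterministic synthetic label volumes and sections with known ground
truth, used to exercise the spatial-analysis pipeline."""

from __future__ import annotations

import numpy as np


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> np.ndarray:
    """Build a synthetic binary volume or section.

    Kinds: ``solid_cube`` (edge, n), ``hollow_shell`` (outer, thickness, n),
    ``digital_disc_section`` (radius_px, n), ``random_binary`` (n, p),
    ``checker_rim`` (n).
    """
    p = dict(params or {})
    if kind == "solid_cube":
        n = p.get("n", 20)
        edge = p.get("edge", 8)
        vol = np.zeros((n, n, n), np.uint8)
        lo = (n - edge) // 2
        vol[lo : lo + edge, lo : lo + edge, lo : lo + edge] = 1
        return vol
    if kind == "hollow_shell":
        n = p.get("n", 20)
        outer = p.get("outer", 12)
        thickness = p.get("thickness", 3)
        vol = np.zeros((n, n, n), np.uint8)
        lo = (n - outer) // 2
        vol[lo : lo + outer, lo : lo + outer, lo : lo + outer] = 1
        ilo = lo + thickness
        ihi = lo + outer - thickness
        vol[ilo:ihi, ilo:ihi, ilo:ihi] = 0
        return vol
    if kind == "digital_disc_section":
        n = p.get("n", 48)
        r = p.get("radius_px", 15)
        c = n // 2
        yy, xx = np.mgrid[0:n, 0:n]
        return ((yy - c) ** 2 + (xx - c) ** 2 <= r**2).astype(np.uint8)
    if kind == "random_binary":
        n = p.get("n", 16)
        density = p.get("p", 0.5)
        shape = (n, n) if p.get("ndim", 3) == 2 else (n, n, n)
        rng = np.random.default_rng(seed)
        return (rng.random(shape) < density).astype(np.uint8)
    if kind == "checker_rim":
        n = p.get("n", 32)
        sec = np.zeros((n, n), np.uint8)
        lo, hi = n // 4, 3 * n // 4
        sec[lo:hi, lo:hi] = 1
        return sec
    raise ValueError(f"unknown fixture kind {kind!r}")
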