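"""T-cell entry points and the neoantigen-driven recruitment rate.

The tumour vasculature is reduced to a static set of entry voxels whose
density decays exponentially with depth from the lattice boundary at rate
``lambda_vasc`` (per um): each voxel at depth d is an entry point with
probability ``base_density * exp(-lambda * d)``.  Lymph-node priming and
trafficking are collapsed into the phenomenological recruitment rate

    rate(D) = r_base * k_a * (k_i * D) / (1 + k_i * D)      [arrivals / h]

where D is the cumulative number of dead cancer cells (the antigen-release
signal), k_a the mutational burden (a capacity: more neoantigen clones mean
proportionally more recruitable specificities) and k_i the antigen strength
(an affinity: stronger antigens saturate the response at a smaller dead-cell
signal).  The rate is zero without dead-cell signal and saturates at
``r_base * k_a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LatticeConfig, RuleParameters
from .errors import ConfigurationError


@dataclass
class VasculatureMap:
    """Entry voxels plus the density law they were drawn from."""

    entry_voxels: np.ndarray  # (k, 3) int
    lambda_vasc_per_um: float
    base_density: float
    n_voxels_per_edge: int
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.entry_voxels = np.asarray(self.entry_voxels, dtype=np.int64).reshape(-1, 3)
        n = self.n_voxels_per_edge
        if self.entry_voxels.size and (
            self.entry_voxels.min() < 0 or self.entry_voxels.max() >= n
        ):
            raise ConfigurationError("entry voxel outside the lattice")

    @property
    def n_entries(self) -> int:
        return int(self.entry_voxels.shape[0])

    def depths_um(self) -> np.ndarray:
        """Depth of each entry voxel: distance to the nearest lattice face, um."""
        return depth_to_face_um(
            self.entry_voxels, self.n_voxels_per_edge, self.voxel_size_um
        )

    def to_csv(self, path) -> None:
        """Write the entry voxels as a CSV list (x, y, z, depth_um)."""
        depths = self.depths_um()
        with open(path, "w") as fh:
            fh.write("x,y,z,depth_um\n")
            for (x, y, z), d in zip(self.entry_voxels, depths):
                fh.write(f"{x},{y},{z},{d:g}\n")


def depth_to_face_um(voxels: np.ndarray, n: int, voxel_size_um: float) -> np.ndarray:
    v = np.asarray(voxels).reshape(-1, 3)
    d = np.minimum(v, n - 1 - v).min(axis=1)
    return d * voxel_size_um


def entry_probability_grid(
    config: LatticeConfig, lambda_vasc_per_um: float, base_density: float
) -> np.ndarray:
    """Per-voxel entry-point probability ``base_density * exp(-lambda d)``."""
    n = config.n_voxels_per_edge
    idx = np.arange(n)
    d1 = np.minimum(idx, n - 1 - idx)  # per-axis distance to face, voxels
    depth = np.minimum.reduce(np.meshgrid(d1, d1, d1, indexing="ij"))
    return base_density * np.exp(-lambda_vasc_per_um * depth * config.voxel_size_um)


def place_entry_points(
    config: LatticeConfig,
    lambda_vasc_per_um: float,
    seed,
    base_density: float = 0.02,
) -> VasculatureMap:
    """Draw the static entry-point set; ``seed`` is an int or a Generator."""
    if lambda_vasc_per_um < 0:
        raise ConfigurationError("lambda_vasc must be >= 0")
    if not 0.0 <= base_density <= 1.0:
        raise ConfigurationError("base_density must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = entry_probability_grid(config, lambda_vasc_per_um, base_density)
    mask = rng.random(p.shape) < p
    entries = np.argwhere(mask)
    return VasculatureMap(
        entry_voxels=entries,
        lambda_vasc_per_um=lambda_vasc_per_um,
        base_density=base_density,
        n_voxels_per_edge=config.n_voxels_per_edge,
        voxel_size_um=config.voxel_size_um,
    )


def recruitment_rate(
    params: RuleParameters, cumulative_dead: int | float
) -> float:
    """Expected effector arrivals per hour given the dead-cell signal."""
    if cumulative_dead < 0:
        raise ValueError("cumulative_dead must be >= 0")
    d = float(cumulative_dead)
    return params.r_base * params.k_a * (params.k_i * d) / (1.0 + params.k_i * d)
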