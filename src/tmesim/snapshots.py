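"""Serialization of run artefacts.

Voxel snapshots go to HDF5 (uint8 label grid with the frozen state->code
table, float64 cytokine grid, int32 agent-id grid) with seed, config hash
and schema version as attributes so any artefact can be traced back to, and
re-run from, its exact configuration.  Time series and event logs are plain
CSV with the documented headers.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import Snapshot
from .errors import SnapshotError

SNAPSHOT_SCHEMA_VERSION = 1


def write_snapshot(path: str | Path, snap: Snapshot) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=snap.labels.astype(np.uint8))
        f.create_dataset("il2", data=snap.il2.astype(np.float64))
        f.create_dataset("ids", data=snap.ids.astype(np.int32))
        f.attrs["schema_version"] = SNAPSHOT_SCHEMA_VERSION
        f.attrs["day"] = float(snap.day)
        f.attrs["clock_h"] = float(snap.clock_h)
        f.attrs["voxel_size_um"] = float(snap.voxel_size_um)
        f.attrs["seed"] = -1 if snap.seed is None else int(snap.seed)
        f.attrs["config_hash"] = snap.config_hash or ""


def read_snapshot(path: str | Path) -> Snapshot:
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SNAPSHOT_SCHEMA_VERSION:
                raise SnapshotError(
                    f"snapshot schema version {version} unsupported "
                    f"(expected {SNAPSHOT_SCHEMA_VERSION})"
                )
            seed = int(f.attrs["seed"])
            return Snapshot(
                day=float(f.attrs["day"]),
                clock_h=float(f.attrs["clock_h"]),
                labels=f["labels"][...],
                il2=f["il2"][...],
                ids=f["ids"][...],
                voxel_size_um=float(f.attrs["voxel_size_um"]),
                seed=None if seed < 0 else seed,
                config_hash=str(f.attrs["config_hash"]) or None,
                schema_version=version,
            )
    except SnapshotError:
        raise
    except (OSError, KeyError) as exc:
        raise SnapshotError(f"cannot read snapshot {path}: {exc}") from exc


def write_time_series(path: str | Path, ts: pd.DataFrame) -> None:
    ts.to_csv(path, index=False)


def read_time_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
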