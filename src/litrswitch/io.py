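"""Result serialization: trajectories, grids, and metadata sidecars.

Every artifact is written together with a JSON sidecar carrying the seed,
configuration hash and run settings, so any output file can be regenerated
bit-exactly from its sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import PhaseGrid
from .ssa import Trajectory

__all__ = [
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_phase_grid_csv",
    "write_sidecar",
    "config_hash",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_sidecar(path: str | Path, meta: dict) -> Path:
    sidecar = Path(str(path) + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True,
                                  default=str) + "\n")
    return sidecar


def write_trajectory_tsv(trajectory: Trajectory, path: str | Path) -> Path:
    """Time column plus one integer column per species, tab-separated."""
    path = Path(path)
    df = trajectory.to_frame()
    df.to_csv(path, sep="\t", index=False)
    write_sidecar(path, {
        "seed": trajectory.seed,
        "t_end_s": trajectory.t_end,
        "sample_dt_s": trajectory.sample_dt,
        "absorbed": trajectory.absorbed,
        "network_hash": config_hash(trajectory.network.to_dict()
                                    if not trajectory.network.compile().has_custom
                                    else trajectory.network.metadata),
        "species": trajectory.species,
    })
    return path


def read_trajectory_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phase_grid_csv(grid: PhaseGrid, path: str | Path,
                         meta: dict | None = None) -> Path:
    path = Path(path)
    grid.to_frame().to_csv(path, index=False)
    side = {"axis1": grid.axis1_name, "axis2": grid.axis2_name,
            "shape": list(grid.shape)}
    seeds = grid.cell_meta.get("seeds")
    if seeds is not None:
        side["cell_seeds"] = {f"{i},{j}": list(v) for (i, j), v in seeds.items()}
    for key in ("t_end_s", "sample_dt_s", "base_seed"):
        if key in grid.cell_meta:
            side[key] = grid.cell_meta[key]
    if meta:
        side.update(meta)
    write_sidecar(path, side)
    return path
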