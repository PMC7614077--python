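"""Shared I/O: chunked volumes, CSV graph/forest dialects, JSON reports.

Volumes are stored as zarr arrays with dimension order ``(t, z, y, x)`` or
``(t, z, y, x, c)`` and voxel-size metadata; lineage forests and candidate
graphs travel as plain CSV (``node_id,t,z,y,x,parent_id`` and the
``nodes.csv``/``edges.csv`` pair respectively), so every intermediate of the
pipeline is inspectable and diff-able.  Reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
import zarr

from .candidates import CandidateGraph
from .forest import LineageForest

__all__ = [
    "write_volume",
    "read_volume",
    "write_forest",
    "read_forest",
    "write_graph",
    "read_graph",
    "write_report",
    "load_config",
    "dump_config",
]

_DIM_NAMES = {4: ("t", "z", "y", "x"), 5: ("t", "z", "y", "x", "c")}


def write_volume(path, array: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a 4D (t,z,y,x) or 5D (t,z,y,x,c) array as a zarr store."""
    array = np.asarray(array)
    if array.ndim not in _DIM_NAMES:
        raise ValueError(f"expected 4D or 5D volume, got shape {array.shape}")
    chunks = (1,) + array.shape[1:]
    z = zarr.open(str(path), mode="w", shape=array.shape, dtype=array.dtype,
                  chunks=chunks)
    z[:] = array
    z.attrs["dims"] = list(_DIM_NAMES[array.ndim])
    z.attrs["voxel_size"] = [float(v) for v in voxel_size]
    return Path(path)


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a zarr volume; returns (array, voxel_size). Errors on bad layout."""
    try:
        z = zarr.open(str(path), mode="r")
    except Exception as exc:
        raise IOError(f"cannot open volume store at {path}: {exc}") from exc
    if z.ndim not in _DIM_NAMES:
        raise ValueError(f"volume at {path} has {z.ndim} dims, expected 4 or 5")
    dims = list(z.attrs.get("dims", _DIM_NAMES[z.ndim]))
    if dims != list(_DIM_NAMES[z.ndim]):
        raise ValueError(
            f"volume at {path} has dimension order {dims}, expected "
            f"{list(_DIM_NAMES[z.ndim])}"
        )
    voxel_size = tuple(z.attrs.get("voxel_size", (1.0, 1.0, 1.0)))
    return z[:], voxel_size


def write_forest(path, forest: LineageForest) -> Path:
    forest.write_csv(path)
    return Path(path)


def read_forest(path, validate: bool = True) -> LineageForest:
    return LineageForest.read_csv(path, validate=validate)


def write_graph(out_dir, graph: CandidateGraph) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph.write_csv(out / "nodes.csv", out / "edges.csv")
    return out


def read_graph(graph_dir) -> CandidateGraph:
    d = Path(graph_dir)
    return CandidateGraph.read_csv(d / "nodes.csv", d / "edges.csv")


def write_report(path, report: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(path, config: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path
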