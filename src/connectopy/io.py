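"""File I/O: HDF5 containers for arrays, CSV for tidy results.

An optional GIFTI/CIFTI adapter (requiring nibabel) is provided for real
surface data; nothing else in the package depends on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import Fingerprints
from .embeddings import EmbeddingResult
from .simulate import RetinotopicGrid, SimulationConfig, Timeseries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_fingerprints",
    "read_fingerprints",
    "write_embedding",
    "read_embedding",
    "write_simulation_fixture",
    "read_simulation_fixture",
    "export_ground_truth_csv",
    "records_to_frame",
    "read_gifti_timeseries",
]


def write_timeseries(path, ts: Timeseries, fmt: str = "hdf5") -> None:
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=ts.data)
            f.create_dataset("run_offsets", data=np.asarray(ts.run_offsets))
    elif fmt == "csv":
        with open(path, "w") as f:
            f.write("# run_offsets: " + ",".join(map(str, ts.run_offsets)) + "\n")
            np.savetxt(f, ts.data, delimiter=",")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_timeseries(path, fmt: str = "hdf5") -> Timeseries:
    """Load a Timeseries; run-boundary metadata is required, not inferred."""
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "run_offsets" not in f:
                raise ValueError(f"{path}: missing run_offsets dataset")
            data = f["data"][()]
            offsets = [int(v) for v in f["run_offsets"][()]]
        return Timeseries(data, offsets)
    if fmt == "csv":
        with open(path) as f:
            header = f.readline()
            if not header.startswith("# run_offsets:"):
                raise ValueError(f"{path}: missing run_offsets header line")
            offsets = [int(v) for v in header.split(":", 1)[1].split(",")]
            data = np.loadtxt(f, delimiter=",", ndmin=2)
        return Timeseries(data, offsets)
    if fmt == "gifti":
        return read_gifti_timeseries(path)
    raise ValueError(f"unknown format: {fmt!r}")


def write_fingerprints(path, fp: Fingerprints) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=fp.values)
        d.attrs["source_mode"] = fp.source_mode
        d.attrs["pca_applied"] = fp.pca_applied
        d.attrs["split_id"] = fp.split_id or ""


def read_fingerprints(path) -> Fingerprints:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return Fingerprints(
            d[()],
            source_mode=str(d.attrs["source_mode"]),
            pca_applied=bool(d.attrs["pca_applied"]),
            split_id=str(d.attrs["split_id"]) or None,
        )


def write_embedding(path, result: EmbeddingResult) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("components", data=result.components)
        d.attrs["algorithm"] = result.algorithm
        d.attrs["params"] = json.dumps(result.params)
        g = f.create_group("diagnostics")
        for key, val in result.diagnostics.items():
            g.create_dataset(key, data=np.asarray(val))


def read_embedding(path) -> EmbeddingResult:
    with h5py.File(path, "r") as f:
        d = f["components"]
        diagnostics = {k: f["diagnostics"][k][()] for k in f["diagnostics"]}
        return EmbeddingResult(
            d[()],
            str(d.attrs["algorithm"]),
            json.loads(d.attrs["params"]),
            diagnostics,
        )


def write_simulation_fixture(
    path,
    grid: RetinotopicGrid,
    config: SimulationConfig,
    roi_ts: Timeseries,
    nonroi: dict[str, Timeseries] | None = None,
) -> None:
    """One HDF5 container holding a complete synthetic dataset."""
    with h5py.File(path, "w") as f:
        f.create_dataset("roi_timeseries", data=roi_ts.data)
        f.create_dataset("run_offsets", data=np.asarray(roi_ts.run_offsets))
        f.create_dataset("ecc", data=grid.ecc)
        f.create_dataset("polar", data=grid.polar)
        f.attrs["grid_shape"] = grid.grid_shape
        f.attrs["config"] = json.dumps(config.to_dict())
        if nonroi:
            g = f.create_group("nonroi_timeseries")
            for key, ts in nonroi.items():
                g.create_dataset(key, data=ts.data)


def read_simulation_fixture(path):
    with h5py.File(path, "r") as f:
        config = SimulationConfig(**{
            **json.loads(f.attrs["config"]),
            "grid_shape": tuple(json.loads(f.attrs["config"])["grid_shape"]),
        })
        grid = RetinotopicGrid(
            f["ecc"][()], f["polar"][()], tuple(int(v) for v in f.attrs["grid_shape"])
        )
        offsets = [int(v) for v in f["run_offsets"][()]]
        roi_ts = Timeseries(f["roi_timeseries"][()], offsets)
        nonroi = {}
        if "nonroi_timeseries" in f:
            for key in f["nonroi_timeseries"]:
                nonroi[key] = Timeseries(f["nonroi_timeseries"][key][()], offsets)
    return grid, config, roi_ts, nonroi


def export_ground_truth_csv(path, grid: RetinotopicGrid) -> None:
    pd.DataFrame(
        {"vertex": np.arange(grid.vertex_count), "ecc": grid.ecc, "polar": grid.polar}
    ).to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    """AccuracyRecords as a tidy DataFrame (one row per observation)."""
    return pd.DataFrame([r.to_dict() for r in records])


def read_gifti_timeseries(path, run_offsets=None) -> Timeseries:
    """Optional adapter for surface ``.func.gii`` files (requires nibabel).

    Each darray is one timepoint; without explicit ``run_offsets`` the file
    is treated as a single run.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.column_stack([d.data for d in img.darrays])
    return Timeseries(data, run_offsets or [0, data.shape[1]])
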