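"""Persistence: HDF5 dataset containers, SREM stacks, PNG export, run records.

Layout of a dataset file (schema version 1)::

    /                     attrs: schema_version, kind="dataset"
    /samples/<sample_id>  attrs: subject_id, posture, blanket, trial
        <radar_id>        2D float array (n_bins, n_pulses), attrs: bin_length

A stack file stores per-sample view stacks as (n_views, H, W) arrays with
the radar order and grid recorded as file attributes.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .labels import coarse_map
from .preprocess import RadarFrame
from .simulate import SampleRecord

__all__ = [
    "SCHEMA_VERSION",
    "DataError",
    "save_dataset",
    "load_dataset",
    "save_stacks",
    "load_stacks",
    "export_srem_png",
    "write_run_record",
]

SCHEMA_VERSION = 1


class DataError(RuntimeError):
    """Raised when a container is missing expected content."""


def save_dataset(records, path) -> pd.DataFrame:
    """Write SampleRecords to HDF5; returns the manifest DataFrame."""
    rows = []
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "dataset"
        grp = f.create_group("samples")
        for rec in records:
            g = grp.create_group(rec.sample_id)
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["posture"] = rec.posture
            g.attrs["blanket"] = rec.blanket
            g.attrs["trial"] = rec.trial
            for rid, frame in rec.frames.items():
                d = g.create_dataset(rid, data=frame.values)
                d.attrs["bin_length"] = frame.bin_length
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "subject_id": rec.subject_id,
                    "posture": rec.posture,
                    "coarse_label": coarse_map(rec.posture),
                    "blanket": rec.blanket,
                    "trial": rec.trial,
                }
            )
    return pd.DataFrame(rows)


def load_dataset(path, expected_radars=None):
    """Read SampleRecords back; returns (records, manifest DataFrame).

    ``expected_radars``: radar ids that must be present in every sample;
    a missing one raises DataError naming it.
    """
    records, rows = [], []
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise DataError(
                f"dataset schema version {version} unsupported (expected {SCHEMA_VERSION})"
            )
        for sid in f["samples"]:
            g = f["samples"][sid]
            frames = {}
            for rid in g:
                frames[rid] = RadarFrame(
                    values=g[rid][()], radar_id=rid, bin_length=float(g[rid].attrs["bin_length"])
                )
            if expected_radars is not None:
                missing = [r for r in expected_radars if r not in frames]
                if missing:
                    raise DataError(f"sample {sid} missing radar group(s): {missing}")
            rec = SampleRecord(
                subject_id=str(g.attrs["subject_id"]),
                posture=str(g.attrs["posture"]),
                blanket=str(g.attrs["blanket"]),
                trial=int(g.attrs["trial"]),
                frames=frames,
            )
            records.append(rec)
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "subject_id": rec.subject_id,
                    "posture": rec.posture,
                    "coarse_label": coarse_map(rec.posture),
                    "blanket": rec.blanket,
                    "trial": rec.trial,
                }
            )
    return records, pd.DataFrame(rows)


def save_stacks(path, x, sample_meta: pd.DataFrame, radar_ids, grid) -> None:
    """Write per-sample view stacks: x is (n_samples, n_views, H, W)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "stacks"
        f.attrs["radar_ids"] = [str(r) for r in radar_ids]
        f.attrs["grid_extent"] = list(grid.extent)
        f.attrs["grid_cell_size"] = grid.cell_size
        f.create_dataset("x", data=np.asarray(x, dtype=np.float32), compression="gzip")
        meta = f.create_group("meta")
        for col in sample_meta.columns:
            vals = sample_meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals)


def load_stacks(path):
    """Returns (x, meta DataFrame, radar_ids)."""
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise DataError("stack file schema version mismatch")
        x = f["x"][()]
        cols = {}
        for col in f["meta"]:
            v = f["meta"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        radar_ids = tuple(str(r) for r in f.attrs["radar_ids"])
    return x, pd.DataFrame(cols), radar_ids


def export_srem_png(srem, path) -> None:
    """8-bit grayscale PNG, min-max scaled; constant maps export all-zero.

    Image rows run along the bed length (headboard at the top), so the
    file has shape (n_y, n_x).
    """
    values = np.asarray(srem.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    lo, hi = values.min(), values.max()
    scaled = np.zeros_like(values) if hi <= lo else (values - lo) / (hi - lo)
    img = (scaled.T * 255.0).round().astype(np.uint8)  # (n_y, n_x)
    Image.fromarray(img, mode="L").save(path)


def write_run_record(out_dir, command: str, config: dict, seed) -> Path:
    """Machine-readable provenance next to every CLI output."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"run_{command}.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
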