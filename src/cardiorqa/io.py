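"""HDF5 containers for recordings/trace grids and CSV tables for features."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .sim import PotentialRecording, TissueGeometry, TraceGrid

__all__ = ["save_recording", "load_recording", "save_traces", "load_traces",
           "save_features", "load_features", "save_metric_map_csv"]


def save_recording(path, rec: PotentialRecording,
                   attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("u", data=rec.u, compression="gzip",
                             compression_opts=1)
        d.attrs["dt_sample_ms"] = rec.dt_sample_ms
        f.attrs["size_cm"] = rec.geometry.size_cm
        f.attrs["dx_mm"] = rec.geometry.dx_mm
        if rec.geometry.damage is not None:
            f.create_dataset("damage", data=rec.geometry.damage,
                             compression="gzip", compression_opts=1)
        if rec.final_state is not None:
            g = f.create_group("final_state")
            for name, arr in zip("uvw", rec.final_state):
                g.create_dataset(name, data=arr)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_recording(path) -> PotentialRecording:
    try:
        with h5py.File(path, "r") as f:
            u = f["u"][...]
            dt = float(f["u"].attrs["dt_sample_ms"])
            damage = f["damage"][...].astype(bool) if "damage" in f else None
            geom = TissueGeometry(size_cm=tuple(f.attrs["size_cm"]),
                                  dx_mm=float(f.attrs["dx_mm"]),
                                  damage=damage)
            final = None
            if "final_state" in f:
                g = f["final_state"]
                final = tuple(g[name][...] for name in "uvw")
    except (OSError, KeyError) as exc:
        raise IOError(f"cannot read recording container {path!r}: {exc}") \
            from exc
    return PotentialRecording(u=u, dt_sample_ms=dt, geometry=geom,
                              final_state=final)


def save_traces(path, tg: TraceGrid, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=tg.traces, compression="gzip",
                         compression_opts=1)
        f.create_dataset("valid", data=tg.valid)
        f.attrs["spacing_mm"] = tg.spacing_mm
        f.attrs["fs_hz"] = tg.fs_hz
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_traces(path) -> TraceGrid:
    try:
        with h5py.File(path, "r") as f:
            return TraceGrid(traces=f["traces"][...],
                             valid=f["valid"][...].astype(bool),
                             spacing_mm=float(f.attrs["spacing_mm"]),
                             fs_hz=float(f.attrs["fs_hz"]))
    except (OSError, KeyError) as exc:
        raise IOError(f"cannot read trace container {path!r}: {exc}") from exc


def save_features(path, features: pd.DataFrame) -> None:
    cols = [c for c in features.columns if c != "class"]
    if "class" in features.columns:
        cols.append("class")
    features[cols].to_csv(path, index=False)


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_metric_map_csv(path, metric_map) -> None:
    """Matrix CSV of a metric map (nan at invalid sites)."""
    vals = np.where(metric_map.valid, metric_map.values, np.nan)
    np.savetxt(path, vals, delimiter=",")
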