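"""Plain-text interchange formats.

Everything is CSV/JSON with explicit headers so that desk-scale runs stay
inspectable: tracking signals as ``t_ms,value[,tx,ty,theta,sx,sy,...]``,
list-mode events as ``t_ms,x_mm,y_mm,z_mm`` with a gate-tag sidecar
(``<stem>.tags.csv``), transforms as the JSON records of the transforms
module, and voxel grids as raw counts with a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import GridSpec, ListModeStream, PhaseImage, TrackingSignal
from .transforms import ImageToProbeTransform, RigidTransform3D

__all__ = [
    "read_tracking_signal", "write_tracking_signal",
    "read_listmode", "write_listmode",
    "read_transform", "write_transform",
    "read_phase_image", "write_phase_image",
]

_SIGNAL_COLS = ("t_ms", "value")


def write_tracking_signal(signal: TrackingSignal, path) -> None:
    df = pd.DataFrame({"t_ms": signal.times_ms, "value": signal.values})
    for k, v in signal.extras.items():
        df[k] = v
    df.to_csv(path, index=False, float_format="%.12g")


def read_tracking_signal(path) -> TrackingSignal:
    df = pd.read_csv(path)
    for col in _SIGNAL_COLS:
        if col not in df.columns:
            raise ValueError(f"tracking-signal CSV lacks column {col!r}")
    extras = {c: df[c].to_numpy() for c in df.columns if c not in _SIGNAL_COLS}
    return TrackingSignal(times_ms=df["t_ms"].to_numpy(),
                          values=df["value"].to_numpy(), extras=extras)


def _tags_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(".tags.csv")


def write_listmode(lm: ListModeStream, path) -> None:
    pd.DataFrame({
        "t_ms": lm.times_ms,
        "x_mm": lm.positions_mm[:, 0],
        "y_mm": lm.positions_mm[:, 1],
        "z_mm": lm.positions_mm[:, 2],
    }).to_csv(path, index=False, float_format="%.9g")
    pd.DataFrame({"t_ms": lm.gate_tags_ms}).to_csv(
        _tags_path(path), index=False, float_format="%.9g")


def read_listmode(path) -> ListModeStream:
    df = pd.read_csv(path)
    for col in ("t_ms", "x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise ValueError(f"list-mode CSV lacks column {col!r}")
    tags = np.empty(0)
    tp = _tags_path(path)
    if tp.exists():
        tags = pd.read_csv(tp)["t_ms"].to_numpy(float)
    return ListModeStream(
        times_ms=df["t_ms"].to_numpy(float),
        positions_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        gate_tags_ms=tags)


def write_transform(t, path) -> None:
    Path(path).write_text(json.dumps(t.to_json_dict(), indent=1))


def read_transform(path):
    d = json.loads(Path(path).read_text())
    if "scale_mm_per_px" in d:
        return ImageToProbeTransform.from_json_dict(d)
    return RigidTransform3D.from_json_dict(d)


def write_phase_image(img: PhaseImage, path) -> None:
    """Raw little-endian float64 counts plus a ``.json`` header sidecar."""
    p = Path(path)
    img.counts.astype("<f8").tofile(p)
    header = {
        "shape": list(img.grid.shape),
        "voxel_mm": img.grid.voxel_mm,
        "origin_mm": list(img.grid.origin_mm),
        "phase_index": img.phase_index,
        "dtype": "<f8",
    }
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(header, indent=1))


def read_phase_image(path) -> PhaseImage:
    p = Path(path)
    header = json.loads(p.with_suffix(p.suffix + ".json").read_text())
    counts = np.fromfile(p, dtype=header["dtype"]).reshape(header["shape"])
    grid = GridSpec(origin_mm=tuple(header["origin_mm"]),
                    voxel_mm=header["voxel_mm"],
                    shape=tuple(header["shape"]))
    return PhaseImage(counts=counts, grid=grid,
                      phase_index=header.get("phase_index", 0))
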