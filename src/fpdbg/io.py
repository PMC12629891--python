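"""Reading and writing frame stacks (multi-page TIFF / HDF5) with JSON sidecar
metadata, timeline JSON, and fixed-precision CSV/JSON table export."""

from __future__ import annotations

import json
import os
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synth import FrameSequence
from .timeline import BeamTimeline

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_timeline",
    "read_timeline",
    "sidecar_path",
    "format_float",
    "write_table_csv",
    "write_json",
]

_META_VERSION = 1


def sidecar_path(path: str) -> str:
    root, _ = os.path.splitext(path)
    return root + ".meta.json"


def _meta_payload(seq: FrameSequence, include_spikes: bool) -> dict:
    payload = {
        "version": _META_VERSION,
        "n_frames": int(len(seq)),
        "n_rows": int(seq.frames.shape[1]),
        "n_cols": int(seq.frames.shape[2]),
        "dtype": str(seq.frames.dtype),
        "frame_period_s": float(seq.frame_period),
        "frames": [
            {
                "frame": int(row.frame),
                "time_s": float(row.time),
                "xray": bool(row.xray),
                "beam_overlap": float(row.beam_overlap),
            }
            for row in seq.meta.itertuples()
        ],
    }
    if include_spikes and seq.spikes is not None:
        payload["spikes"] = [
            [[int(r), int(c), float(i)] for r, c, i in frame_spikes]
            for frame_spikes in seq.spikes
        ]
    return payload


def write_frame_stack(
    seq: FrameSequence,
    path: str,
    meta_path: Optional[str] = None,
    include_spikes: bool = False,
) -> str:
    """Write a sequence as multi-page grayscale TIFF (``.tif``/``.tiff``) or
    HDF5 (``.h5``/``.hdf5``, dataset ``frames``) plus a JSON sidecar with the
    per-frame metadata.  Returns the sidecar path."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, seq.frames, photometric="minisblack")
    elif ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=seq.frames)
            ds.attrs["frame_period_s"] = seq.frame_period
            ds.attrs["n_frames"] = len(seq)
    else:
        raise ValueError(f"unsupported frame-stack extension {ext!r}")
    meta_path = meta_path or sidecar_path(path)
    with open(meta_path, "w") as fh:
        json.dump(_meta_payload(seq, include_spikes), fh, indent=1)
    return meta_path


def read_frame_stack(path: str, meta_path: Optional[str] = None) -> FrameSequence:
    """Read a frame stack and its sidecar back into a :class:`FrameSequence`,
    validating shape and dtype against the metadata."""
    meta_path = meta_path or sidecar_path(path)
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"missing sidecar metadata file {meta_path}")
    with open(meta_path) as fh:
        payload = json.load(fh)

    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise IOError(f"failed to read TIFF stack {path}: {exc}") from exc
    elif ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            frames = fh["frames"][()]
    else:
        raise ValueError(f"unsupported frame-stack extension {ext!r}")

    frames = np.atleast_3d(frames)
    if frames.ndim == 3 and frames.shape[0] != payload["n_frames"] and frames.shape[-1] == payload["n_frames"]:
        frames = np.moveaxis(frames, -1, 0)
    expected = (payload["n_frames"], payload["n_rows"], payload["n_cols"])
    if frames.shape != expected:
        raise ValueError(
            f"frame stack shape {frames.shape} does not match metadata {expected}"
            f" (read stopped at frame {frames.shape[0]})"
        )
    if str(frames.dtype) != payload["dtype"]:
        raise ValueError(
            f"frame dtype {frames.dtype} does not match metadata {payload['dtype']}"
        )
    meta = pd.DataFrame(
        [
            {
                "frame": m["frame"],
                "time": m["time_s"],
                "xray": m["xray"],
                "beam_overlap": m["beam_overlap"],
            }
            for m in payload["frames"]
        ]
    )
    spikes = None
    if "spikes" in payload:
        spikes = [np.asarray(s, dtype=float).reshape(-1, 3) for s in payload["spikes"]]
    return FrameSequence(
        frames=frames, meta=meta, frame_period=payload["frame_period_s"], spikes=spikes
    )


def write_timeline(timeline: BeamTimeline, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(timeline.to_dict(), fh, indent=1)


def read_timeline(path: str) -> BeamTimeline:
    with open(path) as fh:
        return BeamTimeline.from_dict(json.load(fh))


def format_float(x: float) -> str:
    """Fixed 6-significant-digit formatting for reproducible text outputs."""
    if isinstance(x, float):
        if x != x:  # NaN
            return "nan"
        return f"{x:.6g}"
    return str(x)


def write_table_csv(df: pd.DataFrame, path: str) -> None:
    """CSV export with stable 6-significant-digit float formatting."""
    df.to_csv(path, index=False, float_format="%.6g")


def _round_json(obj):
    if isinstance(obj, dict):
        return {k: _round_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_json(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if x != x or x in (float("inf"), float("-inf")) else float(f"{x:.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_json(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: dict, path: str) -> None:
    """JSON export with floats rounded to 6 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_json(obj), fh, indent=1, sort_keys=True)
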