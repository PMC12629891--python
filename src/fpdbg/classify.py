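"""Frame taxonomy: A/B/C with X-ray superscript from the beam timeline.

A frame is **A** when its integration window does not overlap the irradiation
session at all (acquired before/after it), **B** when the window overlaps a
proton beam-on interval — any nonzero overlap counts, so partial-exposure
beam-start/stop frames are B — and **C** when it sits inside the session but
overlaps only pauses.  The superscript +/- records whether an X-ray pulse falls
in the window.  All interval tests use half-open ``[on, off)`` semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeline import BeamTimeline

__all__ = ["FrameLabel", "classify_frames", "label_string"]


@dataclass(frozen=True)
class FrameLabel:
    category: str  # "A", "B" or "C"
    xray: bool

    def __post_init__(self) -> None:
        if self.category not in ("A", "B", "C"):
            raise ValueError(f"unknown category {self.category!r}")

    def __str__(self) -> str:
        return f"{self.category}{'+' if self.xray else '-'}"


def label_string(category: str, xray: bool) -> str:
    return str(FrameLabel(category, bool(xray)))


def classify_frames(meta: pd.DataFrame, timeline: BeamTimeline,
                    frame_period: float) -> pd.DataFrame:
    """Label every frame of a sequence from the timeline.

    ``meta`` needs columns ``frame`` and ``time`` (window start, s; the window
    is ``[time, time + frame_period)`` on the timeline's clock).  Returns a
    DataFrame with columns ``frame``, ``label``, ``category``, ``xray``,
    ``beam_overlap`` and ``pause_overlap`` (fractions of the window).
    """
    if frame_period <= 0:
        raise ValueError("frame_period must be positive")
    # Overlap fractions below this are floating-point slivers from windows
    # abutting interval boundaries; treating them as zero keeps labels stable
    # under consistent time-origin shifts.
    eps = 1e-9
    rows = []
    for frame, t0 in zip(meta["frame"].to_numpy(), meta["time"].to_numpy()):
        t1 = t0 + frame_period
        beam = min(timeline.beam_overlap(t0, t1) / frame_period, 1.0)
        session = min(timeline.session_overlap(t0, t1) / frame_period, 1.0)
        if beam <= eps:
            beam = 0.0
        if session <= eps:
            session = 0.0
        pause = max(session - beam, 0.0)
        if beam > 0:
            cat = "B"
        elif session > 0:
            cat = "C"
        else:
            cat = "A"
        xray = timeline.pulses_in(t0, t1).size > 0
        rows.append(
            {
                "frame": int(frame),
                "label": label_string(cat, xray),
                "category": cat,
                "xray": bool(xray),
                "beam_overlap": float(beam),
                "pause_overlap": float(pause),
            }
        )
    return pd.DataFrame(rows)
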