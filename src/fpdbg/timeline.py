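"""Beam/X-ray timeline construction and half-open interval arithmetic.

A :class:`BeamTimeline` holds the X-ray pulse train and the proton beam-on
intervals of one irradiation session.  A synchrotron extracts protons in spills
separated by pauses (energy-layer transitions and the extraction duty cycle);
because the two radiation sources must not fire simultaneously, the proton beam
is additionally halted for a short window around every X-ray pulse.

All intervals are half-open ``[on, off)`` in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import TimingConfig

__all__ = [
    "BeamTimeline",
    "build_timeline",
    "subtract_intervals",
    "intersect_length",
    "total_length",
]


# -- interval arithmetic (half-open [a, b) on the real line) -----------------

def _as_interval_array(intervals) -> np.ndarray:
    a = np.asarray(intervals, dtype=float)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array of [on, off) pairs")
    return a


def _merge(intervals: np.ndarray) -> np.ndarray:
    if intervals.size == 0:
        return intervals
    ivs = intervals[np.argsort(intervals[:, 0])]
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.asarray(out)


def subtract_intervals(base, cuts) -> np.ndarray:
    """Set difference ``base \\ union(cuts)`` for half-open interval unions."""
    base = _as_interval_array(base)
    cuts = _merge(_as_interval_array(cuts))
    out: list[tuple[float, float]] = []
    for a, b in base:
        lo = a
        for c, d in cuts:
            if d <= lo or c >= b:
                continue
            if c > lo:
                out.append((lo, min(c, b)))
            lo = max(lo, d)
            if lo >= b:
                break
        if lo < b:
            out.append((lo, b))
    return _as_interval_array(out)


def intersect_length(intervals, lo: float, hi: float) -> float:
    """Total measure of ``intervals`` inside the window ``[lo, hi)``."""
    ivs = _as_interval_array(intervals)
    if ivs.size == 0:
        return 0.0
    a = np.maximum(ivs[:, 0], lo)
    b = np.minimum(ivs[:, 1], hi)
    return float(np.clip(b - a, 0.0, None).sum())


def total_length(intervals) -> float:
    ivs = _as_interval_array(intervals)
    if ivs.size == 0:
        return 0.0
    return float((ivs[:, 1] - ivs[:, 0]).sum())


# -- timeline ----------------------------------------------------------------

@dataclass(frozen=True)
class BeamTimeline:
    """X-ray pulse times and proton beam-on intervals of one session."""

    xray_pulses: np.ndarray          # pulse start times, s
    xray_pulse_width: float          # s
    beam_intervals: np.ndarray       # (n, 2) half-open beam-on intervals, s
    session_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        pulses = np.sort(np.asarray(self.xray_pulses, dtype=float))
        object.__setattr__(self, "xray_pulses", pulses)
        beams = _as_interval_array(self.beam_intervals)
        if beams.size:
            order = np.argsort(beams[:, 0])
            beams = beams[order]
            if np.any(beams[:, 1] <= beams[:, 0]):
                raise ValueError("beam intervals must have positive length")
            if np.any(beams[1:, 0] < beams[:-1, 1]):
                raise ValueError("beam intervals must be disjoint")
        object.__setattr__(self, "beam_intervals", beams)
        lo, hi = self.session_bounds
        if hi < lo:
            raise ValueError("session_bounds must be ordered")
        object.__setattr__(self, "session_bounds", (float(lo), float(hi)))

    @property
    def pause_intervals(self) -> np.ndarray:
        """Complement of beam-on within the session bounds: the pause tiling."""
        lo, hi = self.session_bounds
        return subtract_intervals([(lo, hi)], self.beam_intervals)

    def beam_overlap(self, lo: float, hi: float) -> float:
        """Beam-on seconds inside the window ``[lo, hi)``."""
        return intersect_length(self.beam_intervals, lo, hi)

    def session_overlap(self, lo: float, hi: float) -> float:
        return intersect_length([self.session_bounds], lo, hi)

    def pulses_in(self, lo: float, hi: float) -> np.ndarray:
        """Pulse start times whose pulse interval overlaps ``[lo, hi)``."""
        p = self.xray_pulses
        return p[(p + self.xray_pulse_width > lo) & (p < hi)]

    def to_dict(self) -> dict:
        return {
            "xray_pulses_s": [float(t) for t in self.xray_pulses],
            "xray_pulse_width_s": float(self.xray_pulse_width),
            "beam_intervals_s": [[float(a), float(b)] for a, b in self.beam_intervals],
            "session_bounds_s": [float(self.session_bounds[0]), float(self.session_bounds[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamTimeline":
        return cls(
            xray_pulses=np.asarray(d["xray_pulses_s"], dtype=float),
            xray_pulse_width=float(d["xray_pulse_width_s"]),
            beam_intervals=np.asarray(d["beam_intervals_s"], dtype=float).reshape(-1, 2),
            session_bounds=tuple(d["session_bounds_s"]),
        )


def build_timeline(
    timing: TimingConfig,
    layer_plan: Sequence[tuple[float, float]],
    session_start: float = 0.0,
    xray_extent: float | None = None,
) -> BeamTimeline:
    """Build a session timeline from a spill/pause plan.

    ``layer_plan`` is a sequence of ``(spill_duration, pause_duration)`` pairs
    laid out back to back from ``session_start``.  X-ray pulses run at exact
    ``timing.xray_rate`` spacing from time 0 through the session (and up to
    ``xray_extent`` when given, so frames after the last spill keep their pulse
    train).  The proton beam is carved out of each spill around every pulse by
    the mutual-exclusion halt window, so no beam-on instant coincides with a
    pulse +/- halt.
    """
    plan = [(float(s), float(p)) for s, p in layer_plan]
    if not plan:
        raise ValueError("layer_plan must contain at least one (spill, pause) entry")
    for s, p in plan:
        if s <= 0:
            raise ValueError("spill durations must be positive")
        if p < 0:
            raise ValueError("pause durations must be nonnegative")

    spills = []
    t = float(session_start)
    for s, p in plan:
        spills.append((t, t + s))
        t += s + p
    session_end = spills[-1][1]

    if timing.xray_rate > 0:
        period = timing.xray_period
        phase = timing.effective_xray_phase
        extent = session_end if xray_extent is None else max(xray_extent, session_end)
        n = int(math.floor((extent - phase) / period)) + 1
        pulses = phase + period * np.arange(max(n, 0))
        pulses = pulses[pulses < extent]
        # Mutual-exclusion halt: centered on the pulse, total width >= pulse width.
        half = 0.5 * max(timing.proton_halt_around_xray, timing.xray_pulse_width)
        centers = pulses + 0.5 * timing.xray_pulse_width
        halts = np.column_stack([centers - half, centers + half])
        beams = subtract_intervals(spills, halts)
    else:
        pulses = np.empty(0)
        beams = _as_interval_array(spills)

    return BeamTimeline(
        xray_pulses=pulses,
        xray_pulse_width=timing.xray_pulse_width,
        beam_intervals=beams,
        session_bounds=(float(session_start), float(session_end)),
    )
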