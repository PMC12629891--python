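"""Synthetic flat-panel-detector frame sequences with proton/X-ray timing.

The generator stands in for measured data: it renders 16-bit frames at the
panel's frame rate, alternating X-ray / no-X-ray frames (pulse rate = half the
frame rate), with dark/thermal noise, a handful of fixed hot pixels, and sparse
secondary-radiation background spikes whose intensities follow the truncated
exponential law ``N(I) = k * exp(-lam * I)`` on ``(0, i_max]``.  Spikes are
produced by a homogeneous event process during proton beam-on and are assigned
to frames through the panel's row-readout windows, which is what creates the
spatially biased background in beam-start/stop frames under the rolling
periphery-to-center scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import BGModel, DetectorConfig, ReadoutModel, SceneModel, TimingConfig
from .timeline import BeamTimeline, intersect_length

__all__ = [
    "FrameSequence",
    "sample_spike_events",
    "scene_field",
    "render_frame",
    "assign_events_with_readout",
    "sample_event_times",
    "simulate_sequence",
]

#: 3x3 cluster kernel for the optional multi-pixel spike footprint
#: (center-heavy; weights sum to 1).
CLUSTER3_KERNEL = np.array(
    [[0.025, 0.075, 0.025],
     [0.075, 0.600, 0.075],
     [0.025, 0.075, 0.025]]
)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _frame_dtype(det: DetectorConfig):
    return np.uint16 if det.bit_depth <= 16 else np.uint32


@dataclass
class FrameSequence:
    """An ordered stack of rendered frames with per-frame timing metadata.

    ``meta`` has one row per frame: ``frame`` index, ``time`` (window start,
    s), ``xray`` (pulse within the integration window), ``beam_overlap``
    (fraction of the window covered by proton beam-on).  ``spikes`` is the
    optional ground-truth channel: per frame, an ``(n, 3)`` float array of
    (row, col, intensity) for every background event, kept for testing.
    """

    frames: np.ndarray
    meta: pd.DataFrame
    frame_period: float
    spikes: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, n_rows, n_cols) array")
        if len(self.meta) != len(self.frames):
            raise ValueError("metadata length must match the number of frames")
        t = self.meta["time"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def sample_spike_events(bg: BGModel, n_events: int, rng_seed) -> np.ndarray:
    """Draw spike intensities from the truncated exponential law.

    Intensities are i.i.d. with density proportional to ``exp(-lam * I)`` on
    ``(0, i_max]``, sampled by inverse CDF; reproducible under a fixed seed.
    """
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    rng = _rng(rng_seed)
    u = rng.random(int(n_events))
    z = 1.0 - np.exp(-bg.lam * bg.i_max)
    return -np.log1p(-u * z) / bg.lam


def scene_field(scene: SceneModel, det: DetectorConfig) -> np.ndarray:
    """Mean X-ray brightness map for a scene, counts per pixel."""
    if scene.mode == "dark" or scene.mean_intensity == 0:
        return np.zeros((det.n_rows, det.n_cols))
    if scene.mode == "uniform":
        return np.full((det.n_rows, det.n_cols), scene.mean_intensity)
    # phantom_like: smooth radial profile normalized to the requested mean
    r = np.linspace(-1, 1, det.n_rows)[:, None]
    c = np.linspace(-1, 1, det.n_cols)[None, :]
    profile = 0.45 + np.exp(-(r**2 + c**2) / 0.55)
    profile /= profile.mean()
    return scene.mean_intensity * profile


def render_frame(
    det: DetectorConfig,
    scene: Optional[SceneModel],
    spikes,
    rng_seed,
    footprint: str = "single",
) -> np.ndarray:
    """Compose one frame: dark noise + scene + spikes + hot pixels, rounded
    and clipped to the ADC range.

    ``spikes`` is a sequence of ``(row, col, intensity)``; co-located spikes
    add before clipping.  ``footprint`` is ``single`` (default) or
    ``cluster3`` (3x3 kernel spread).
    """
    rng = _rng(rng_seed)
    canvas = np.zeros((det.n_rows, det.n_cols))
    if det.dark_sigma > 0:
        canvas += rng.normal(det.dark_mean, det.dark_sigma, canvas.shape)
    else:
        canvas += det.dark_mean
    if scene is not None and scene.mode != "dark":
        mean_map = scene_field(scene, det)
        canvas += mean_map
        sigma = scene.noise_sigma
        if sigma is None:
            sigma_map = np.sqrt(scene.gain * np.clip(mean_map, 0, None))
            if np.any(sigma_map > 0):
                canvas += rng.normal(0.0, 1.0, canvas.shape) * sigma_map
        elif sigma > 0:
            canvas += rng.normal(0.0, sigma, canvas.shape)

    spikes = np.asarray(spikes, dtype=float).reshape(-1, 3)
    if len(spikes):
        rows = spikes[:, 0].astype(np.intp)
        cols = spikes[:, 1].astype(np.intp)
        if rows.min() < 0 or rows.max() >= det.n_rows or cols.min() < 0 or cols.max() >= det.n_cols:
            raise ValueError("spike coordinates out of detector bounds")
        if footprint == "single":
            np.add.at(canvas, (rows, cols), spikes[:, 2])
        elif footprint == "cluster3":
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    w = CLUSTER3_KERNEL[dr + 1, dc + 1]
                    rr = np.clip(rows + dr, 0, det.n_rows - 1)
                    cc = np.clip(cols + dc, 0, det.n_cols - 1)
                    np.add.at(canvas, (rr, cc), w * spikes[:, 2])
        else:
            raise ValueError(f"unknown spike footprint {footprint!r}")

    for r, c, offset in det.hot_pixels:
        canvas[r, c] += offset

    return np.clip(np.rint(canvas), 0, det.saturation).astype(_frame_dtype(det))


def assign_events_with_readout(
    times,
    readout: ReadoutModel,
    det: DetectorConfig,
    frame_period: float,
    n_frames: int,
    rng_seed,
    strict: bool = True,
):
    """Place events uniformly on the panel and bin them into frames through
    per-row integration windows.

    Row ``r``'s window for frame ``f`` is ``[f*T + off[r], (f+1)*T + off[r])``
    with ``off`` from the readout scheme (all zeros under ``global``); windows
    of one row tile time exactly.  Returns ``(frame_idx, rows, cols)`` arrays.
    With ``strict`` (default), an event falling outside every frame's windows
    raises; otherwise such events are dropped.  Returns
    ``(frame_idx, rows, cols, event_idx)`` with ``event_idx`` the indices of
    the retained events in the input order.
    """
    times = np.asarray(times, dtype=float)
    rng = _rng(rng_seed)
    rows = rng.integers(0, det.n_rows, size=times.size)
    cols = rng.integers(0, det.n_cols, size=times.size)
    off = readout.row_offsets(det.n_rows, frame_period)
    fidx = np.floor((times - off[rows]) / frame_period).astype(np.int64)
    ok = (fidx >= 0) & (fidx < n_frames)
    if strict and not np.all(ok):
        bad = times[~ok][0]
        raise ValueError(f"event at t={bad:.6f}s falls outside every frame window")
    event_idx = np.nonzero(ok)[0]
    return fidx[ok], rows[ok], cols[ok], event_idx


def sample_event_times(
    intervals: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous event process at ``rate`` (events/s) restricted to a union
    of disjoint intervals; returns sorted event times."""
    ivs = np.asarray(intervals, dtype=float).reshape(-1, 2)
    lengths = np.clip(ivs[:, 1] - ivs[:, 0], 0, None)
    total = lengths.sum()
    if total <= 0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * total)
    u = rng.random(n) * total
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    idx = np.searchsorted(cum, u, side="right") - 1
    idx = np.clip(idx, 0, len(lengths) - 1)
    return np.sort(ivs[idx, 0] + (u - cum[idx]))


def simulate_sequence(
    det: DetectorConfig,
    timing: TimingConfig,
    timeline: BeamTimeline,
    scene: Optional[SceneModel],
    bg: BGModel,
    readout: ReadoutModel,
    n_frames: int,
    rng_seed: int,
    footprint: str = "single",
    keep_ground_truth: bool = True,
) -> FrameSequence:
    """Simulate a full frame sequence.

    Frame ``f`` integrates ``[f*T, (f+1)*T)`` on the session clock (per-row
    shifted under rolling readout).  The expected spike count of a frame equals
    ``bg.expected_events(n_pixels)`` times its beam-overlap fraction; the X-ray
    flag is set iff a pulse overlaps the frame window, and the scene is rendered
    only in X-ray frames.  Fully reproducible: the session seed spawns one
    substream for the event process and one per frame for pixel noise.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    T = timing.frame_integration
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_frames + 2)
    ev_rng = np.random.default_rng(children[0])
    place_rng = np.random.default_rng(children[1])

    # Event process over beam-on time; pad one frame so late row windows of the
    # last frame are fed, then drop assignments outside [0, n_frames).
    span_hi = (n_frames + 1) * T
    beams = timeline.beam_intervals
    if beams.size:
        clipped = np.column_stack(
            [np.clip(beams[:, 0], 0.0, span_hi), np.clip(beams[:, 1], 0.0, span_hi)]
        )
        clipped = clipped[clipped[:, 1] > clipped[:, 0]]
    else:
        clipped = np.empty((0, 2))
    rate = bg.expected_events(det.n_pixels) / T  # events per second at full coverage
    times = sample_event_times(clipped, rate, ev_rng)
    intensities = sample_spike_events(bg, times.size, ev_rng)
    fidx, rows, cols, event_idx = assign_events_with_readout(
        times, readout, det, T, n_frames, place_rng, strict=False
    )
    intensities = intensities[event_idx]
    order = np.argsort(fidx, kind="stable")
    fidx, rows, cols, intensities = fidx[order], rows[order], cols[order], intensities[order]
    bounds = np.searchsorted(fidx, np.arange(n_frames + 1))

    frames = np.empty((n_frames, det.n_rows, det.n_cols), dtype=_frame_dtype(det))
    spikes_per_frame: list[np.ndarray] = []
    meta_rows = []
    for f in range(n_frames):
        lo, hi = f * T, (f + 1) * T
        xray = timeline.pulses_in(lo, hi).size > 0
        overlap = min(timeline.beam_overlap(lo, hi) / T, 1.0)
        sl = slice(bounds[f], bounds[f + 1])
        frame_spikes = np.column_stack([rows[sl], cols[sl], intensities[sl]])
        frame_scene = scene if xray else None
        frames[f] = render_frame(
            det, frame_scene, frame_spikes, np.random.default_rng(children[2 + f]),
            footprint=footprint,
        )
        spikes_per_frame.append(frame_spikes)
        meta_rows.append(
            {"frame": f, "time": lo, "xray": bool(xray), "beam_overlap": float(overlap)}
        )

    meta = pd.DataFrame(meta_rows)
    return FrameSequence(
        frames=frames,
        meta=meta,
        frame_period=T,
        spikes=spikes_per_frame if keep_ground_truth else None,
    )
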