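"""Reproduction studies: canned experiments that regenerate the characterized
background quantities from scratch.

Each study builds its own synthetic inputs at the characterized conditions
(768 x 768 panel, 30 fps / 15 pps timing, background law k = 0.017 %/count,
lam = 0.014 /count), runs the measurement pipeline, and returns the derived
numbers.  They are the basis of the acceptance script and of the end-to-end
tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .characterize import (
    affected_fraction,
    fit_exponential,
    hot_pixel_mask_from_config,
    pooled_histogram,
)
from .classify import classify_frames
from .config import BGModel, DetectorConfig, ReadoutModel, SceneModel, TimingConfig
from .synth import render_frame, sample_spike_events, simulate_sequence
from .timeline import build_timeline

__all__ = ["dark_frame_characterization", "scene_bg_impact"]


def dark_frame_characterization(
    seed: int,
    layer_plan: Sequence[tuple[float, float]] = ((5.0, 1.0), (5.0, 1.0), (5.0, 1.0)),
    session_start: float = 0.5,
    det: Optional[DetectorConfig] = None,
    timing: Optional[TimingConfig] = None,
    bg: Optional[BGModel] = None,
    fit_lo: float = 100.0,
    fit_hi: float = 300.0,
    i_max: float = 1000.0,
) -> dict:
    """Simulate a dark irradiation session and recover the background law.

    Generates a dark-scene frame sequence spanning the spill plan (the default
    three 5-s spills give >= 200 fully-beam-covered B- frames), pools those
    frames' pixels into a width-1 histogram above the median baseline, fits
    ``ln N(I)`` over the fit window and integrates the fitted model.

    Returns a dict with ``k_hat`` (%), ``lambda_hat`` (/count),
    ``affected_percent``, ``affected_percent_discrete``, ``n_frames_pooled``
    and ``n_pixels_pooled``.
    """
    det = det or DetectorConfig()
    timing = timing or TimingConfig()
    bg = bg or BGModel()
    T = timing.frame_integration
    session_end = session_start + sum(s + p for s, p in layer_plan)
    n_frames = int(np.ceil(session_end / T)) + 2
    timeline = build_timeline(
        timing, layer_plan, session_start=session_start, xray_extent=n_frames * T
    )
    seq = simulate_sequence(
        det, timing, timeline, None, bg, ReadoutModel(scheme="global"),
        n_frames, seed,
    )
    labels = classify_frames(seq.meta, timeline, seq.frame_period)
    full = labels[
        (labels["category"] == "B")
        & (~labels["xray"])
        & (labels["beam_overlap"] >= 0.999)
    ]["frame"].to_numpy()
    mask = hot_pixel_mask_from_config(det)
    hist = pooled_histogram(seq.frames[full], mask=mask, baseline="median")
    fit = fit_exponential(hist, fit_lo, fit_hi)
    af = affected_fraction(fit, i_max)
    return {
        "k_hat": fit.k_hat,
        "lambda_hat": fit.lam_hat,
        "affected_percent": af.percent,
        "affected_percent_discrete": af.percent_discrete,
        "rms_log_residual": fit.rms_log_residual,
        "baseline": hist.baseline,
        "n_frames_pooled": int(full.size),
        "n_pixels_pooled": hist.total_pixels,
    }


def scene_bg_impact(
    seed: int,
    scene_means: Sequence[float] = (195.9, 335.7),
    n_frames: int = 20,
    det: Optional[DetectorConfig] = None,
    bg: Optional[BGModel] = None,
) -> dict:
    """Relative mean-intensity increase when full-coverage background is added
    to uniform scenes of typical clinical X-ray brightness.

    For each scene mean, renders ``n_frames`` frames without background and
    ``n_frames`` with background events at the full-frame rate, and computes
    ``(mean_with - mean_without) / mean_without * 100``.

    Returns ``{"relative_increase_pct": {mean: value}, "max_relative_increase_pct": v,
    "n_frames_per_scene": n_frames}``.
    """
    det = det or DetectorConfig()
    bg = bg or BGModel()
    mask = hot_pixel_mask_from_config(det)
    base_events = bg.expected_events(det.n_pixels)
    ss = np.random.SeedSequence(seed)
    out: dict[float, float] = {}
    for mean, child in zip(scene_means, ss.spawn(len(scene_means))):
        rng = np.random.default_rng(child)
        scene = SceneModel(mode="uniform", mean_intensity=float(mean))
        m_without = np.empty(n_frames)
        m_with = np.empty(n_frames)
        for f in range(n_frames):
            frame0 = render_frame(det, scene, [], rng)
            n_ev = rng.poisson(base_events)
            spikes = np.column_stack(
                [
                    rng.integers(0, det.n_rows, n_ev),
                    rng.integers(0, det.n_cols, n_ev),
                    sample_spike_events(bg, n_ev, rng),
                ]
            )
            frame1 = render_frame(det, scene, spikes, rng)
            m_without[f] = frame0[~mask].mean()
            m_with[f] = frame1[~mask].mean()
        out[float(mean)] = float(
            (m_with.mean() - m_without.mean()) / m_without.mean() * 100.0
        )
    return {
        "relative_increase_pct": out,
        "max_relative_increase_pct": max(out.values()),
        "n_frames_per_scene": int(n_frames),
    }
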