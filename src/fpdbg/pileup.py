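"""Virtual-FPD pile-up study.

Background events drawn from the exponential intensity law are accumulated on
a virtual 768 x 768 pixel matrix at multiples of the normal dose rate
("normal" = the occupancy the characterized model implies per frame).
Co-located events add before ADC clipping, so at high multipliers coincidence
sums lift the histogram tail and the single-event law no longer holds.  Each
multiplier is refit and the deviation from the (dose-scaled) reference law is
quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .characterize import ExpFitResult, fit_exponential, pooled_histogram
from .config import BGModel, DetectorConfig
from .synth import sample_spike_events

__all__ = ["PileupConfig", "EventLedger", "accumulate_bg", "pileup_scan"]


@dataclass(frozen=True)
class PileupConfig:
    multipliers: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    frames_per_multiplier: int = 8
    fit_lo: float = 100.0
    fit_hi: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "multipliers", tuple(float(m) for m in self.multipliers))
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be positive")
        if self.frames_per_multiplier < 1:
            raise ValueError("frames_per_multiplier must be >= 1")


@dataclass
class EventLedger:
    """Ground truth of one accumulation: per-pixel event counts, the sampled
    events, and the pre-clipping charge sums."""

    event_counts: np.ndarray     # (rows, cols) number of events per pixel
    pixel_index: np.ndarray      # flat pixel index per event
    intensities: np.ndarray      # per-event intensity
    presum: np.ndarray           # (rows, cols) summed intensity before clipping

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)

    def collision_fraction(self) -> float:
        """Fraction of pixels carrying >= 2 events."""
        return float((self.event_counts >= 2).mean())


def accumulate_bg(
    multiplier: float,
    bg: BGModel,
    det: DetectorConfig,
    rng_seed,
) -> tuple[np.ndarray, EventLedger]:
    """One virtual-FPD frame at ``multiplier`` times the normal dose rate.

    ``Poisson(multiplier * base_events)`` events are placed uniformly at
    random; co-located intensities add, then the pixel is clipped at the ADC
    saturation.  No dark noise or scene — pure BG accumulation.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    base = bg.expected_events(det.n_pixels)
    n = rng.poisson(multiplier * base)
    pix = rng.integers(0, det.n_pixels, size=n)
    intens = sample_spike_events(bg, n, rng)
    presum = np.zeros(det.n_pixels)
    np.add.at(presum, pix, intens)
    counts = np.bincount(pix, minlength=det.n_pixels)
    frame = np.clip(np.rint(presum), 0, det.saturation)
    frame = frame.astype(np.uint16 if det.bit_depth <= 16 else np.uint32)
    shape = (det.n_rows, det.n_cols)
    ledger = EventLedger(
        event_counts=counts.reshape(shape),
        pixel_index=pix,
        intensities=intens,
        presum=presum.reshape(shape),
    )
    return frame.reshape(shape), ledger


def _deviation_vs_reference(
    fit: ExpFitResult, multiplier: float, bg: BGModel, lo: float, hi: float
) -> float:
    """RMS distance in log space between the fitted curve and the dose-scaled
    reference law ``multiplier * k * exp(-lam * I)`` over the fit window.

    Comparing fitted curves rather than raw sparse bins keeps the metric's
    noise floor at the parameter-uncertainty level, so pile-up departure is
    resolved well above counting noise.
    """
    grid = np.arange(lo, hi + 1.0)
    delta = (np.log(fit.k_hat) - fit.lam_hat * grid) - (
        np.log(multiplier * bg.k) - bg.lam * grid
    )
    return float(np.sqrt(np.mean(delta**2)))


def pileup_scan(
    cfg: PileupConfig, bg: BGModel, det: DetectorConfig
) -> pd.DataFrame:
    """Scan the multiplier ladder: accumulate, pool histograms, refit, and
    quantify the departure from the single-event law.

    Returns one row per multiplier with the fitted parameters, the headline
    ``deviation`` metric (RMS of ln N vs the dose-scaled reference law over
    the fit window), the own-fit RMS log-residual, the relative lambda shift,
    the collision fraction (pixels with >= 2 events) and the saturated-pixel
    fraction.  A fit failure (e.g. everything saturated) is recorded as a row
    with ``ok = False``, never raised.
    """
    ss = np.random.SeedSequence(cfg.rng_seed)
    rows = []
    for mult, child in zip(cfg.multipliers, ss.spawn(len(cfg.multipliers))):
        rng = np.random.default_rng(child)
        # Statistics per frame grow with the multiplier, so fewer pooled
        # frames are needed at high dose rates (bounds total event work).
        n_f = max(1, int(round(cfg.frames_per_multiplier / mult)))
        frames = np.empty((n_f, det.n_rows, det.n_cols), dtype=np.uint32)
        coll = np.empty(n_f)
        sat = np.empty(n_f)
        for f in range(n_f):
            frame, ledger = accumulate_bg(mult, bg, det, rng)
            frames[f] = frame
            coll[f] = ledger.collision_fraction()
            sat[f] = float((frame >= det.saturation).mean())
        del ledger
        hist = pooled_histogram(frames)
        row = {
            "multiplier": mult,
            "collision_fraction": float(coll.mean()),
            "saturated_fraction": float(sat.mean()),
        }
        try:
            fit = fit_exponential(hist, cfg.fit_lo, cfg.fit_hi)
        except ValueError as exc:
            row.update(
                k_hat=float("nan"),
                lambda_hat=float("nan"),
                rms_log_residual=float("nan"),
                lambda_shift=float("nan"),
                deviation=float("nan"),
                ok=False,
                message=str(exc),
            )
        else:
            row.update(
                k_hat=fit.k_hat,
                lambda_hat=fit.lam_hat,
                rms_log_residual=fit.rms_log_residual,
                lambda_shift=abs(fit.lam_hat / bg.lam - 1.0),
                deviation=_deviation_vs_reference(fit, mult, bg, cfg.fit_lo, cfg.fit_hi),
                ok=fit.ok,
                message=fit.message,
            )
        rows.append(row)
    return pd.DataFrame(rows)
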