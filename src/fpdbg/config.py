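"""Configuration types for the detector, timing, scene, background and readout models.

All components are frozen dataclasses with validation at construction time, so a
config object that exists is a valid one.  :class:`RunConfig` bundles them and
round-trips losslessly through YAML with every defaulted field serialized
explicitly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

__all__ = [
    "DetectorConfig",
    "TimingConfig",
    "SceneModel",
    "BGModel",
    "ReadoutModel",
    "AnalysisConfig",
    "RunConfig",
    "DEFAULT_HOT_PIXELS",
]

#: Five fixed bright pixels with large, pixel-specific offsets (row, col, offset
#: in counts).  Positions are arbitrary but fixed so hot-pixel masking is testable.
DEFAULT_HOT_PIXELS: tuple[tuple[int, int, float], ...] = (
    (100, 200, 800.0),
    (650, 90, 1200.0),
    (400, 400, 650.0),
    (50, 700, 950.0),
    (700, 600, 700.0),
)


@dataclass(frozen=True)
class DetectorConfig:
    """Geometry and signal range of the flat-panel detector.

    Defaults describe a 768 x 768 (2x2-binned) panel digitized at 16 bit with a
    dark/thermal level around 5 counts and five fixed hot pixels.
    """

    n_rows: int = 768
    n_cols: int = 768
    bit_depth: int = 16
    dark_mean: float = 5.0
    dark_sigma: float = 1.0
    hot_pixels: tuple[tuple[int, int, float], ...] = DEFAULT_HOT_PIXELS

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one row and one column")
        if not 1 <= self.bit_depth <= 32:
            raise ValueError("bit_depth must be in [1, 32]")
        if self.dark_mean < 0:
            raise ValueError("dark_mean must be nonnegative")
        if self.dark_sigma < 0:
            raise ValueError("dark_sigma must be nonnegative")
        object.__setattr__(
            self, "hot_pixels", tuple((int(r), int(c), float(o)) for r, c, o in self.hot_pixels)
        )
        for r, c, _ in self.hot_pixels:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"hot pixel ({r}, {c}) out of bounds")

    @property
    def saturation(self) -> int:
        """ADC full scale, 2**bit_depth - 1."""
        return (1 << self.bit_depth) - 1

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class TimingConfig:
    """Frame / X-ray pulse timing.

    The default mirrors a 30 fps panel with 15 pps pulsed X-ray exposure (3 ms
    pulses), so frames alternate with/without X-ray.  The proton beam is halted
    for ``proton_halt_around_xray`` seconds around each X-ray pulse (mutual
    exclusion of the two sources); the exact halt duration is vendor-undisclosed,
    20 ms is the working default.
    """

    frame_rate: float = 30.0
    xray_rate: float = 15.0
    xray_pulse_width: float = 3e-3
    proton_halt_around_xray: float = 20e-3
    #: Pulse start offset within the session clock; ``None`` centers each pulse
    #: in its frame so the halt window stays inside the X-ray frame.
    xray_phase: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.xray_rate < 0:
            raise ValueError("xray_rate must be nonnegative")
        if self.xray_pulse_width < 0 or self.proton_halt_around_xray < 0:
            raise ValueError("pulse width and halt duration must be nonnegative")
        if self.xray_rate > 0 and self.xray_pulse_width >= self.frame_integration:
            raise ValueError("xray_pulse_width must be shorter than the frame integration time")

    @property
    def frame_integration(self) -> float:
        """Integration window length per frame, s (1 / frame_rate)."""
        return 1.0 / self.frame_rate

    @property
    def xray_period(self) -> float:
        if self.xray_rate <= 0:
            raise ValueError("no X-ray pulses when xray_rate == 0")
        return 1.0 / self.xray_rate

    @property
    def effective_xray_phase(self) -> float:
        if self.xray_phase is not None:
            return self.xray_phase
        return 0.5 * (self.frame_integration - self.xray_pulse_width)


@dataclass(frozen=True)
class BGModel:
    """Exponential model of the secondary-radiation background.

    The percentage of detector pixels at intensity ``I`` (counts above the
    non-spike baseline) attributable to BG is ``N(I) = k * exp(-lam * I)`` with
    percentage amplitude ``k`` and decay coefficient ``lam``, truncated at
    ``i_max``.  Defaults are the characterized values k = 0.017 %/count,
    lam = 0.014 /count, i_max = 1000 counts.
    """

    k: float = 0.017
    lam: float = 0.014
    i_max: float = 1000.0
    #: Expected spike count for a frame fully covered by beam-on.  ``None``
    #: derives it from the model's implied affected-pixel percentage.
    events_per_full_frame: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")
        if self.events_per_full_frame is not None and self.events_per_full_frame < 0:
            raise ValueError("events_per_full_frame must be nonnegative")

    @property
    def affected_percent(self) -> float:
        """Closed-form integral of N(I) over (0, i_max], in % of pixels."""
        return (self.k / self.lam) * (1.0 - math.exp(-self.lam * self.i_max))

    @property
    def mean_intensity(self) -> float:
        """Mean of the truncated exponential spike-intensity law, counts."""
        z = 1.0 - math.exp(-self.lam * self.i_max)
        return 1.0 / self.lam - self.i_max * math.exp(-self.lam * self.i_max) / z

    def expected_events(self, n_pixels: int) -> float:
        """Expected spikes per fully-beam-covered frame of ``n_pixels`` pixels.

        Defaults to the occupancy the model implies (collisions neglected at
        the 1x rate), i.e. ``n_pixels * affected_percent / 100``.
        """
        if self.events_per_full_frame is not None:
            return self.events_per_full_frame
        return n_pixels * self.affected_percent / 100.0


@dataclass(frozen=True)
class SceneModel:
    """X-ray scene rendered in frames that carry an X-ray pulse.

    ``mode`` is one of ``dark`` (no X-ray signal), ``uniform`` (flat field at
    ``mean_intensity``) or ``phantom_like`` (smooth 2-D brightness map with the
    same mean).  Scene shot noise is Gaussian with sigma = ``noise_sigma`` when
    given, else ``sqrt(gain * mean)``.
    """

    mode: str = "dark"
    mean_intensity: float = 0.0
    noise_sigma: Optional[float] = None
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("dark", "uniform", "phantom_like"):
            raise ValueError(f"unknown scene mode {self.mode!r}")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be nonnegative")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")


@dataclass(frozen=True)
class ReadoutModel:
    """Row-readout scheme of the panel.

    ``global`` (default) gives every row the same integration window, so a
    frame's expected spike count is exactly the full-frame rate times its
    beam-overlap fraction.  ``rolling_periphery_to_center`` reads the top half
    top-down and the bottom half bottom-up at constant row time — the minimal
    model of a tiled panel whose pixel charges are read sequentially from the
    periphery toward the center.  Rolling readout shifts each row's window
    into the neighbouring frames, so with the X-ray mutual-exclusion halts
    active no frame is fully beam-covered in every row; use it for
    beam-start/stop spatial-bias studies, and the global scheme for rate and
    histogram characterization.
    """

    scheme: str = "global"

    def __post_init__(self) -> None:
        if self.scheme not in ("global", "rolling_periphery_to_center"):
            raise ValueError(f"unknown readout scheme {self.scheme!r}")

    def row_offsets(self, n_rows: int, frame_period: float):
        """Per-row readout offset within the frame period, seconds.

        Row ``r``'s integration window for frame ``f`` is
        ``[f*T + off[r], (f+1)*T + off[r])`` — exactly one frame period long and
        tiling time without gaps.
        """
        import numpy as np

        if self.scheme == "global":
            return np.zeros(n_rows)
        half = (n_rows + 1) // 2
        row_time = frame_period / half
        r = np.arange(n_rows)
        return np.where(r < half, r, n_rows - 1 - r) * row_time


@dataclass(frozen=True)
class AnalysisConfig:
    """Characterization options: fit window, percentile, dot threshold, regions."""

    fit_lo: float = 100.0
    fit_hi: float = 300.0
    bin_width: float = 1.0
    percentile: float = 99.99
    dot_threshold: float = 100.0
    n_regions: int = 3
    i_max: float = 1000.0
    subtract_baseline: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.fit_lo >= self.fit_hi:
            raise ValueError("fit_lo must be below fit_hi")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.dot_threshold < 0:
            raise ValueError("dot_threshold must be nonnegative")
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: simulate -> classify -> characterize -> pileup."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    scene: SceneModel = field(default_factory=SceneModel)
    bg: BGModel = field(default_factory=BGModel)
    readout: ReadoutModel = field(default_factory=ReadoutModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    #: Spill/pause plan: sequence of (spill_duration_s, pause_duration_s).
    layer_plan: tuple[tuple[float, float], ...] = ((2.0, 0.7), (2.0, 0.7), (2.0, 0.0))
    session_start: float = 0.5
    n_frames: int = 250
    pileup_multipliers: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    pileup_frames: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "layer_plan", tuple((float(s), float(p)) for s, p in self.layer_plan)
        )
        object.__setattr__(
            self, "pileup_multipliers", tuple(float(m) for m in self.pileup_multipliers)
        )
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.pileup_frames < 1:
            raise ValueError("pileup_frames must be >= 1")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"]["hot_pixels"] = [list(h) for h in self.detector.hot_pixels]
        d["layer_plan"] = [list(e) for e in self.layer_plan]
        d["pileup_multipliers"] = list(self.pileup_multipliers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        det = dict(d.get("detector", {}))
        if "hot_pixels" in det:
            det["hot_pixels"] = tuple(tuple(h) for h in det["hot_pixels"])
        kwargs = dict(
            detector=DetectorConfig(**det),
            timing=TimingConfig(**d.get("timing", {})),
            scene=SceneModel(**d.get("scene", {})),
            bg=BGModel(**d.get("bg", {})),
            readout=ReadoutModel(**d.get("readout", {})),
            analysis=AnalysisConfig(**d.get("analysis", {})),
        )
        for key in ("layer_plan", "session_start", "n_frames", "pileup_multipliers",
                    "pileup_frames", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "layer_plan" in kwargs:
            kwargs["layer_plan"] = tuple(tuple(e) for e in kwargs["layer_plan"])
        if "pileup_multipliers" in kwargs:
            kwargs["pileup_multipliers"] = tuple(kwargs["pileup_multipliers"])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        """Serialize with every defaulted field written out explicitly."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Parse a YAML document, file object or path."""
        import os

        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        elif isinstance(source, str) and "\n" in source and not os.path.exists(source):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)
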