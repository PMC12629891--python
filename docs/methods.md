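# Methods

## The background model

The quantity modeled is the secondary-radiation background (BG) that proton
irradiation induces in kV flat-panel-detector (FPD) frames: sparse,
single-pixel intensity spikes from prompt photons (prompt gammas,
bremsstrahlung, annihilation photons) and neutrons reaching the panel. The
per-intensity occupancy follows

    N(I) = k · exp(−λ I),

with `N(I)` the percentage of panel pixels at intensity `I` and defaults
`k = 0.017 %/count`, `λ = 0.014 /count`. `I` is interpreted as counts **above
the local non-spike baseline** (dark level or X-ray scene); at a dark level of
~5 counts the distinction is small but not negligible for the amplitude — a
raw-count fit would inflate `k` by `e^{5λ} ≈ 7 %` — so the characterization
subtracts an estimated baseline (the pooled median of the selected frames)
before binning. The spike-intensity density is the truncated exponential
`∝ e^{−λI}` on `(0, i_max]` with `i_max = 1000` counts, sampled by inverse
CDF. Its mean is `1/λ − i_max·e^{−λ·i_max}/(1 − e^{−λ·i_max}) ≈ 71.43` counts
at the defaults.

**Event-rate convention.** The expected number of spike events in a frame
fully covered by beam-on is the occupancy the law implies:

    events_per_full_frame = n_pixels · (k/λ)(1 − e^{−λ·i_max}) / 100
                          ≈ 589 824 · 1.214 % ≈ 7 162,

treating pixel collisions as negligible at the 1× rate (collision probability
per event ≈ 0.6 %, which biases the refit `λ` by about −0.6 % — well inside
the statistical tolerance of every check here). Per-frame counts are Poisson;
frames partially covered by beam-on scale in proportion to the covered
fraction of their integration window. Events are placed uniformly over the
panel; the measured spatial distribution is unbiased in steady state, and the
chi-square band test (below) guards that null.

**Affected-pixel fraction.** The canonical value is the continuous closed
form `(k/λ)(1 − e^{−λ·i_max})`; a discrete sum `Σ_{I=1..i_max} k·e^{−λI}` is
reported alongside (the two differ by < 2 % at the default parameters:
1.2143 % vs 1.2058 %). With the printed, rounded parameters the closed form
is ≈ 1.21 %, a ~3 % gap below the commonly quoted 1.25 %; the discrepancy is
attributable to rounding of `k` and `λ` to two significant figures before
publication, and both numbers are carried.

## Timing structure

The panel reads at 30 fps (frame integration `T = 33.3 ms`); the pulsed X-ray
source fires at 15 pps with 3 ms pulses, so frames alternate strictly between
with-X-ray (+) and without-X-ray (−). A synchrotron extracts protons in
spills separated by pauses (energy-layer transitions and the extraction duty
cycle); a session is described by a `(spill, pause)` layer plan. Because the
two radiation sources must not fire simultaneously, the proton beam is halted
around every X-ray pulse. The halt duration is vendor-undisclosed; it is
exposed as `TimingConfig.proton_halt_around_xray` with a 20 ms default, and
the halt window is centered on the pulse.

The pulse phase within the frame is likewise unpublished. The default centers
each pulse in its frame, which keeps the 20 ms halt entirely inside the X-ray
frame; consequences: + frames during spills integrate ~13 ms of beam-on
(overlap ≈ 0.4) and − frames a full 33 ms (overlap 1.0), matching the
description of beam-on dark frames as pure-BG frames of full duration.

**Frame taxonomy.** From the timeline, each frame window `[fT, (f+1)T)` is
labeled A (no overlap with the session), B (any nonzero overlap with beam-on
— so partial beam-start/stop frames are B), or C (inside the session,
overlapping only pauses), with the ± superscript from the pulse-in-window
test. All intervals are half-open; overlap fractions below 10⁻⁹ of the frame
period are treated as zero, so labels are stable when both inputs are shifted
by a common time offset despite floating-point slivers at interval
boundaries.

## Readout model

Two schemes are provided. `global` (the default) gives every row the same
integration window, so a frame's expected spike count is exactly the
full-frame rate times its beam-overlap fraction. `rolling_periphery_to_center`
models a tiled panel read sequentially from the periphery toward the center:
the top half is read top-down and the bottom half bottom-up at constant row
time `T/(n_rows/2)`; row `r`'s window for frame `f` is
`[fT + off_r, (f+1)T + off_r)`, exactly one period long and tiling time. When
the beam starts or stops mid-sweep, rows already read show no events while
later rows do — the mechanism behind spatially biased BG in beam-start/stop
frames, and the rolling scheme reproduces that step at the readout position.

The rolling scheme is deliberately **not** the default for rate work: row
windows extend into neighbouring frames, which during spills contain the
mutual-exclusion halts, so under rolling readout no frame is fully
beam-covered in every row (effective − frame coverage ≈ 0.70 at the default
timing). Rate and histogram characterization therefore use the global
shutter; the rolling model is for spatial-bias studies.

## What the generator emulates — and does not

Emulated: frame/pulse timing and mutual exclusion; spill/pause structure;
Gaussian dark noise (mean 5, σ 1 counts, rounded to integers); a handful of
fixed hot pixels with large offsets; Eq.-style spike BG with additive
co-located events and ADC clipping at `2^16 − 1`; X-ray scenes (uniform or a
smooth phantom-like profile) with shot-like Gaussian noise `σ = √(gain·mean)`
rendered only in + frames; optional 3×3 spike footprint (off by default —
observed spikes are isolated single pixels).

Not emulated: physics-based particle transport and energy spectra;
scintillator/photodiode conversion; detector lag; intra-spill extraction
substructure (flat extraction assumed); delayed-photon BG during pauses
(default 0 — pause-frame histograms are indistinguishable from pre-irradiation
ones; a residual rate can be configured via `events_per_full_frame` on a
custom model); anatomy or motion. Consequently, passing tests demonstrate
internal consistency of the model and pipeline — that the analysis recovers
the law it was fed at realistic statistics — not that the law itself holds
for any particular detector; `k` and `λ` must be re-characterized per system.

## Characterization pipeline

- **Histogram**: width-1 bins, half-open, pooled over all unmasked pixels of
  the selected frames, as percentages summing to 100. Pooling is necessary:
  at 1.2 % occupancy a single frame cannot populate the fit window at unit
  bin width.
- **Fit**: ordinary least squares of `ln N(I)` on `I` over populated bins in
  `[100, 300]` (empty bins excluded; unweighted, matching a straight-line fit
  on a log histogram). `k̂ = e^{intercept}`, `λ̂ = −slope`. Fewer than two
  populated bins raises an "insufficient BG statistics" error; a
  non-decreasing tail (`λ̂ ≤ 0`) is returned flagged, never silently.
- **Hot pixels**: a persistent mask — pixels above threshold in ≥ 90 % of
  dark frames, or the configured positions — is excluded from every
  statistic, separating fixed bright pixels from true BG.
- **Percentile time chart**: default N = 99.99 (the top ~59 pixels of 768²),
  sensitive to ~7 000-event frames while immune to the bulk.
- **Dot count**: unmasked pixels strictly above 100 counts; at the default
  law, `e^{−100λ} ≈ 24.7 %` of events exceed the threshold.
- **Variation table**: mean pixel intensity per frame type; beam-on and pause
  types are compared against the matching without-proton baseline (B⁻, C⁻ vs
  A⁻; B⁺, C⁺ vs A⁺), as absolute counts and percent.
- **Spatial uniformity**: above-threshold dots (or ground-truth events)
  counted in three equal-width vertical bands, chi-squared against
  area-proportional expectation; flagged at p < 0.001, and reported as
  insufficient when there are no dots.
- **Shifted overlay**: for X-ray frames the fitted BG curve is translated
  horizontally by the image mean, `k̂·e^{−λ̂(I − mean)}`, because scene
  brightness and BG are independent and additive.

## Pile-up study

A virtual panel accumulates `Poisson(m · events_per_full_frame)` events at
dose multiplier `m`; co-located intensities add before clipping. Per rung the
pooled histogram is refit and three figures are recorded: the collision
fraction (pixels with ≥ 2 events; `1 − e^{−μ} − μe^{−μ}` per pixel in closed
form), the own-fit RMS log-residual, and the headline `deviation` — the RMS
distance in log space between the fitted curve and the dose-scaled reference
`m·k·e^{−λI}` over the fit window. The deviation is computed from the fitted
parameters rather than raw bins so its noise floor is the parameter
uncertainty (~0.02 at 1× with the default pooled statistics) instead of
per-bin counting noise (~0.2–0.5), which would otherwise swamp the small
pile-up signal at low multipliers. The number of pooled frames per rung
scales as `frames_per_multiplier / m` (statistics per frame grow with `m`),
bounding total work across the ladder.

Under the occupancy-anchored rate convention, pile-up is already strong at
100× — the per-pixel event rate is `μ ≈ 1.21`, one third of occupied pixels
hold coincidence sums, and the refit decay coefficient drops to ≈ 0.008 —
and by 1000× the tail inverts (`λ̂ < 0`). The boundary of the single-event
regime in this implementation therefore lies between 10× and 100× of the
normal rate; at 10× the refit `λ̂` is biased by about −6 %, consistent with
the leading-order collision correction `λ̂ ≈ λ(1 − μ/2)`. Where the
single-event law is reported to survive to higher multiples, the implied
"normal" per-accumulation event count is correspondingly lower than the
full-frame occupancy used here; the convention is exposed via
`BGModel.events_per_full_frame` for sensitivity studies.

## Numerical and reproducibility choices

- Coordinates 0-based; times in seconds; all intervals half-open `[on, off)`.
- One session seed; the event process and each frame's pixel noise draw from
  `SeedSequence`-spawned substreams, so sequences are bit-identical under a
  fixed seed and independent of chunking.
- Saturation applies after summation (charge adds, then the ADC clips).
- Frame stacks are written as multi-page 16-bit TIFF or HDF5 (dataset
  `frames`) with a JSON sidecar carrying per-frame timing metadata; readers
  validate shape and dtype against the sidecar and report the frame index
  reached on truncation.
- CSV/JSON outputs use fixed 6-significant-digit formatting so pipeline
  reruns with the same config are byte-identical; the manifest lists every
  output with a SHA-256 checksum.
- Reproduction studies run at reduced problem sizes chosen for statistical
  adequacy: the dark-frame study uses three 5-s spills (225 fully covered
  beam-on dark frames, ~1.6 M spike events), which puts the fit's statistical
  error near 1 % — comfortably inside the 5 % recovery tolerance; the
  scene-impact study uses 20 frames per brightness level, giving a standard
  error on the relative increase two orders of magnitude below the 1 % bound.

## Known limitations

- The two-section periphery-to-center readout is an assumption; real tiled
  panels may interleave differently, changing the shape (not the existence)
  of beam-start/stop bias.
- The halt duration and pulse phase are configurable guesses; duty cycles of
  partially covered frames shift B⁺/B⁻ mean-intensity accounting
  accordingly.
- Dark and scene noise are Gaussian with configurable moments only; real
  FPDs add structured noise (row noise, lag) that is out of scope.
- The exponential law is an empirical fit over 100–300 counts; nothing here
  validates it below 100 counts, where it rides on the noise floor.
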