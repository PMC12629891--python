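# fpdbg — secondary-radiation background in kV flat-panel-detector images during scanning proton beam delivery

During scanning proton therapy, protons interacting with the patient or
phantom generate secondary radiation — prompt gammas, bremsstrahlung,
annihilation photons and neutrons — that reaches the kV X-ray flat-panel
detectors (FPDs) used for fluoroscopic tumor tracking. In the FPD frames this
background (BG) appears as sparse, spatially random single-pixel spikes. Its
per-intensity occupancy is well described by an exponentially decreasing law

```
N(I) = k · exp(−λ · I)
```

where `N(I)` is the percentage of FPD pixels at intensity `I` counts above the
non-spike baseline, with amplitude `k ≈ 0.017 %/count` and decay coefficient
`λ ≈ 0.014 /count` for a synchrotron-based system at clinical dose rates.
Integrating the law over `I ∈ (0, 1000]` gives the affected-pixel fraction,
`(k/λ)(1 − e^{−λ·1000}) ≈ 1.2 %` of the panel — enough to matter for
simulation-trained tumor-tracking models, but contributing `< 1 %` to the mean
intensity of typical clinical-brightness images.

`fpdbg` is for researchers who need this background as a quantitative,
reproducible model — e.g. to inject realistic BG into digitally reconstructed
radiographs for training tracking networks, or to study detector behaviour at
elevated dose rates. It provides:

- **`fpdbg.synth`** — a synthetic FPD frame-sequence generator with the full
  timing structure: 768×768 16-bit frames at 30 fps, 15 pps pulsed X-ray
  exposure (3 ms) so frames alternate with/without X-ray, synchrotron spills
  and pauses, a ~20 ms proton halt around every X-ray pulse (the two sources
  are mutually exclusive), dark/thermal noise, fixed hot pixels, and BG spikes
  drawn from the truncated exponential law and placed through per-row readout
  windows (global shutter or rolling periphery-to-center).
- **`fpdbg.classify`** — frame taxonomy A/B/C (before irradiation / beam-on /
  pause) with X-ray superscript ±, from interval arithmetic on the timeline.
- **`fpdbg.characterize`** — pooled intensity histograms, the log-linear
  exponential fit over the 100–300 count window, affected-pixel fraction,
  percentile time charts, dot counts above threshold, mean-intensity variation
  tables, shifted-fit overlays for X-ray images, and chi-square spatial
  uniformity tests.
- **`fpdbg.pileup`** — a virtual-FPD pile-up study: BG events accumulated on a
  768×768 matrix at 1–10⁴× the normal dose rate, refit per rung, with
  collision fraction and deviation-from-law metrics.
- **`fpdbg.pipeline` / the `fpdbg` CLI** — a reproducible
  simulate → classify → characterize → pileup chain with YAML configs,
  TIFF/HDF5 stacks, CSV/JSON outputs and a checksummed manifest.

## Worked example

Simulate a dark two-spill session on a reduced 256×256 panel, classify and
characterize it, and scan pile-up regimes:

```python
from fpdbg import RunConfig, DetectorConfig, run_pipeline

cfg = RunConfig(
    detector=DetectorConfig(n_rows=256, n_cols=256, hot_pixels=((12, 40, 900.0),)),
    layer_plan=((3.0, 0.5), (3.0, 0.0)),   # two 3-s spills, 0.5-s pause
    session_start=0.5,
    n_frames=220,
    pileup_multipliers=(1.0, 100.0, 1000.0),
    seed=42,
)
run_pipeline(cfg, "demo")
```

`demo/fit.json` (the exponential fit of the pooled beam-on dark frames):

```json
{
 "baseline": 5.0,
 "fit_range": [100.0, 300.0],
 "k_hat_percent": 0.0172558,
 "lambda_hat": 0.0140742,
 "n_bins": 201,
 "ok": true,
 "rms_log_residual": 0.142785
}
```

The generator was configured with `k = 0.017`, `λ = 0.014`; the fit recovers
both within ~1.5 % despite only ~110 pooled dark frames on a small panel.
`demo/affected_fraction.json` integrates the fitted law over 0–1000 counts:

```json
{"i_max": 1000.0, "percent": 1.22606, "percent_discrete": 1.21745}
```

i.e. ~1.2 % of pixels carry BG during beam-on. `demo/pileup.csv` shows the
dose-rate regimes (`lambda_hat` is the refit decay coefficient, `deviation`
the log-space RMS distance of the fitted curve from the dose-scaled law):

```
 multiplier  lambda_hat  deviation  collision_fraction
          1    0.014533   0.073253            0.000090
        100    0.008349   0.357654            0.343460
       1000   -0.013035   4.863340            0.999893
```

At 1× the single-event law holds; by 100× event coincidences on single pixels
(34 % collision fraction) already flatten the apparent decay, and at 1000×
the histogram tail rises with intensity (negative fitted slope) — the law no
longer applies. `demo/variation_table.csv` accounts for the mean-intensity
impact per frame type (dark scene: the BG adds ~0.87 counts to a 5-count
baseline in beam-on frames without X-ray, and proportionally less in the
partially-halted X-ray frames).

The same stages are available from the shell:

```sh
fpdbg simulate --config cfg.yaml --out stack.tiff --timeline timeline.json --seed 1
fpdbg classify --stack stack.tiff --timeline timeline.json --out labels.csv
fpdbg characterize --stack stack.tiff --labels labels.csv --config cfg.yaml --out results/
fpdbg pileup --config cfg.yaml --out pileup.csv
fpdbg run --config cfg.yaml --out results/ --seed 1
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the timing
structure, the event-rate conventions, numerical choices, and what the
synthetic generator does and does not emulate.
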