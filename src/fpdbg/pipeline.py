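"""End-to-end pipeline: simulate -> classify -> characterize -> pileup.

One seed drives every stage; all numeric outputs are written with fixed
6-significant-digit formatting so a rerun with the same config reproduces
byte-identical files.  A manifest records the config, versions, seed and a
checksum of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .characterize import (
    affected_fraction,
    dot_count,
    fit_exponential,
    hot_pixel_mask_from_config,
    mean_variation_table,
    percentile_timechart,
    pooled_histogram,
    spatial_uniformity,
)
from .classify import classify_frames
from .config import RunConfig
from .io import write_frame_stack, write_json, write_table_csv, write_timeline
from .pileup import PileupConfig, pileup_scan
from .synth import simulate_sequence
from .timeline import build_timeline

__all__ = ["run_pipeline", "characterize_run"]

log = logging.getLogger("fpdbg")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def characterize_run(
    frames: np.ndarray,
    labels: pd.DataFrame,
    cfg: RunConfig,
    mask: Optional[np.ndarray] = None,
) -> dict:
    """Characterize a labeled stack: pooled B- histogram, exponential fit,
    affected fraction, percentile time chart, per-frame dot counts, variation
    table and spatial-uniformity report.

    Returns a dict of result tables/objects; a fit with insufficient BG
    statistics is reported (``fit["ok"] = False``), not raised.
    """
    ana = cfg.analysis
    out: dict = {}
    if mask is None:
        mask = hot_pixel_mask_from_config(cfg.detector)

    # Pure-BG selection: fully beam-covered frames without X-ray exposure.
    bsel = labels[(labels["category"] == "B") & (~labels["xray"])]
    full = bsel[bsel["beam_overlap"] >= 0.999]["frame"].to_numpy()
    out["n_bminus_full"] = int(len(full))
    fit = None
    if len(full) > 0:
        hist = pooled_histogram(
            frames[full],
            mask=mask,
            bin_width=ana.bin_width,
            baseline="median" if ana.subtract_baseline else 0.0,
        )
        out["histogram"] = hist
        try:
            fit = fit_exponential(hist, ana.fit_lo, ana.fit_hi)
            out["fit"] = {
                "ok": fit.ok,
                "k_hat_percent": fit.k_hat,
                "lambda_hat": fit.lam_hat,
                "fit_range": [fit.fit_lo, fit.fit_hi],
                "n_bins": fit.n_bins,
                "rms_log_residual": fit.rms_log_residual,
                "baseline": hist.baseline,
                "message": fit.message,
            }
        except ValueError as exc:
            out["fit"] = {"ok": False, "message": str(exc)}
            fit = None
    else:
        out["fit"] = {"ok": False, "message": "no fully-beam-covered B- frames"}

    if fit is not None and fit.ok:
        af = affected_fraction(fit, ana.i_max)
        out["affected_fraction"] = {
            "percent": af.percent,
            "percent_discrete": af.percent_discrete,
            "i_max": af.i_max,
        }

    out["timechart"] = percentile_timechart(frames, ana.percentile, mask=mask)
    out["dot_counts"] = pd.DataFrame(
        {
            "frame": labels["frame"],
            "label": labels["label"],
            "dot_count": [
                dot_count(frames[f], ana.dot_threshold, mask=mask)
                for f in labels["frame"]
            ],
        }
    )

    try:
        out["variation_table"] = mean_variation_table(labels, frames, mask=mask)
    except ValueError as exc:
        out["variation_table_error"] = str(exc)

    bframes = labels[labels["category"] == "B"]["frame"].to_numpy()
    if len(bframes):
        rep = spatial_uniformity(
            frames=frames[bframes],
            n_regions=ana.n_regions,
            threshold=ana.dot_threshold,
            mask=mask,
        )
        out["uniformity"] = {
            "region_counts": rep.region_counts.tolist(),
            "chi2": rep.chi2,
            "p_value": rep.p_value,
            "flagged": rep.flagged,
            "insufficient": rep.insufficient,
        }
    return out


def run_pipeline(cfg: RunConfig, out_dir: str, seed: Optional[int] = None) -> dict:
    """Run all stages with one seed and write the result bundle to ``out_dir``.

    Returns the manifest dict.  A stage failure aborts with the stage name;
    outputs produced so far plus the manifest are persisted.
    """
    seed = cfg.seed if seed is None else int(seed)
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "fpdbg_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": cfg.to_dict(),
        "outputs": {},
        "stages": [],
    }

    def _register(name: str, path: str) -> None:
        manifest["outputs"][name] = {
            "path": os.path.basename(path),
            "sha256": _sha256(path),
        }

    def _finish(status: str, stage: str = "") -> dict:
        manifest["status"] = status
        if stage:
            manifest["failed_stage"] = stage
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        cfg_path = os.path.join(out_dir, "config.yaml")
        cfg.to_yaml(cfg_path)
        _register("config", cfg_path)

        T = cfg.timing.frame_integration
        timeline = build_timeline(
            cfg.timing,
            cfg.layer_plan,
            session_start=cfg.session_start,
            xray_extent=cfg.n_frames * T,
        )
        tl_path = os.path.join(out_dir, "timeline.json")
        write_timeline(timeline, tl_path)
        _register("timeline", tl_path)

        seq = simulate_sequence(
            cfg.detector, cfg.timing, timeline, cfg.scene, cfg.bg, cfg.readout,
            cfg.n_frames, seed,
        )
        stack_path = os.path.join(out_dir, "stack.tiff")
        meta_path = write_frame_stack(seq, stack_path)
        _register("stack", stack_path)
        _register("stack_meta", meta_path)
        manifest["stages"].append(stage)

        stage = "classify"
        log.info("stage %s", stage)
        labels = classify_frames(seq.meta, timeline, seq.frame_period)
        labels_path = os.path.join(out_dir, "labels.csv")
        write_table_csv(labels, labels_path)
        _register("labels", labels_path)
        manifest["stages"].append(stage)

        stage = "characterize"
        log.info("stage %s", stage)
        results = characterize_run(seq.frames, labels, cfg)
        if "histogram" in results:
            hist_path = os.path.join(out_dir, "histogram.csv")
            write_table_csv(results["histogram"].to_frame(), hist_path)
            _register("histogram", hist_path)
        fit_path = os.path.join(out_dir, "fit.json")
        write_json(results["fit"], fit_path)
        _register("fit", fit_path)
        if "affected_fraction" in results:
            af_path = os.path.join(out_dir, "affected_fraction.json")
            write_json(results["affected_fraction"], af_path)
            _register("affected_fraction", af_path)
        tc_path = os.path.join(out_dir, "timechart.csv")
        write_table_csv(results["timechart"], tc_path)
        _register("timechart", tc_path)
        dots_path = os.path.join(out_dir, "dot_counts.csv")
        write_table_csv(results["dot_counts"], dots_path)
        _register("dot_counts", dots_path)
        if "variation_table" in results:
            var_path = os.path.join(out_dir, "variation_table.csv")
            write_table_csv(results["variation_table"], var_path)
            _register("variation_table", var_path)
        if "uniformity" in results:
            uni_path = os.path.join(out_dir, "uniformity.json")
            write_json(results["uniformity"], uni_path)
            _register("uniformity", uni_path)
        manifest["fit_ok"] = bool(results["fit"].get("ok", False))
        if not manifest["fit_ok"]:
            manifest["fit_message"] = results["fit"].get("message", "")
        manifest["stages"].append(stage)

        stage = "pileup"
        log.info("stage %s", stage)
        pcfg = PileupConfig(
            multipliers=cfg.pileup_multipliers,
            frames_per_multiplier=cfg.pileup_frames,
            fit_lo=cfg.analysis.fit_lo,
            fit_hi=cfg.analysis.fit_hi,
            rng_seed=seed,
        )
        ptab = pileup_scan(pcfg, cfg.bg, cfg.detector)
        p_path = os.path.join(out_dir, "pileup.csv")
        write_table_csv(ptab, p_path)
        _register("pileup", p_path)
        manifest["stages"].append(stage)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finish("failed", stage)
        raise

    return _finish("ok")
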