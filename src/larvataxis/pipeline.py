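"""End-to-end pipeline: simulate -> segment -> flash/wave/calcium -> stats.

``run_pipeline`` executes the stages enabled in the config and returns a
JSON-serializable report; with an output directory it also writes the
report, per-stage tables and a log.  All randomness flows from the single
master seed in the config, and the resolved config (with that seed) is
embedded in the report, so identical config + seed give a byte-identical
report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import load_config
from .fixtures import generate_roi_traces, generate_segment_traces
from .fluorescence import dff, peak_response
from .odor import OdorLandscape, OdorSource
from .opto import FlashSchedule, detect_flash_stops, stop_probability
from .peristalsis import classify_flash_outcome, count_waves, detect_segmental_waves
from .segmentation import (
    SegmentationParams,
    classify_run_gradient,
    derive_kinematics,
    distance_to_nearest_source,
    segment_behavior,
    turn_rate,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import two_proportion_ztest

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_landscape", "build_flashes"]


def build_landscape(cfg: dict):
    block = cfg.get("landscape", {})
    if not block.get("enabled", True):
        return None
    sources = [OdorSource((s[0], s[1], s[2]), s[3] if len(s) > 3 else 1.0)
               for s in block["sources"]]
    return OdorLandscape(sources=sources,
                         diffusion_constant=block["diffusion_constant"],
                         release_time=block["release_time"])


def build_flashes(cfg: dict):
    block = cfg.get("flashes", {})
    if not block.get("enabled", False):
        return None
    return FlashSchedule.periodic(n=block["n"], duration=block["duration"],
                                  gap=block["gap"], first_onset=block["first_onset"],
                                  intensity=block["intensity"])


def _sim_config(cfg: dict, genotype: str, seed_offset: int = 0) -> SimulationConfig:
    sim = cfg["simulation"]
    fields = {k: v for k, v in sim.items() if k in SimulationConfig.__dataclass_fields__}
    fields["seed"] = int(sim["seed"]) + seed_offset
    fields["genotype"] = genotype
    land = cfg.get("landscape", {})
    fields.setdefault("gradient_age", land.get("gradient_age", 200.0))
    fields.setdefault("plane_height", land.get("plane_height", 0.0))
    return SimulationConfig(**fields)


def _seg_params(cfg: dict) -> SegmentationParams:
    seg = cfg["segmentation"]
    keys = SegmentationParams.__dataclass_fields__
    return SegmentationParams(**{k: v for k, v in seg.items() if k in keys})


def _round_floats(obj, sig: int = 9):
    """Round floats to ``sig`` significant digits for stable serialization."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if (x == 0 or not np.isfinite(x)) else float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def run_pipeline(config: dict | str | Path | None = None, out_dir=None) -> dict:
    """Run the configured stages; returns (and optionally writes) the report."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
        logging.getLogger("larvataxis").addHandler(handler)

    landscape = build_landscape(cfg)
    flashes = build_flashes(cfg)
    seg_params = _seg_params(cfg)
    smooth = cfg["segmentation"]["smoothing_window"]
    t_eval = cfg["landscape"]["gradient_age"]
    plane = cfg["landscape"]["plane_height"]

    report: dict = {
        "package_version": __version__,
        "config": cfg,
        "cohorts": {},
    }

    cohort_annotations = {}
    for i, block in enumerate(cfg["cohorts"]):
        genotype = block["genotype"]
        sim_cfg = _sim_config(cfg, genotype, seed_offset=1000 * i)
        use_flashes = flashes if genotype == "chrimson" else None
        cohort = simulate_cohort(sim_cfg, n=int(block["n"]), landscape=landscape,
                                 flashes=use_flashes)
        annotated = []
        rates = []
        for traj, truth in cohort:
            kin = derive_kinematics(traj, smoothing_window=smooth)
            ann = segment_behavior(kin, seg_params)
            if landscape is not None:
                _, dcdt = landscape.concentration_along_path(
                    traj, "centroid", plane_height=plane, static_time=t_eval)
                classify_run_gradient(ann, dcdt)
            annotated.append((traj, truth, kin, ann))
            rates.append(turn_rate(ann, kin))
        cohort_annotations[block["name"]] = annotated

        summary = {
            "n_larvae": len(cohort),
            "genotype": genotype,
            "turns_per_min": float(np.mean([r["turns_per_min"] for r in rates])),
            "turns_per_cm": float(np.nanmean([r["turns_per_cm"] for r in rates])),
        }
        for cls in ("UP", "DOWN"):
            per_min = [r["by_gradient_class"][cls]["turns_per_min"] for r in rates]
            per_min = [v for v in per_min if np.isfinite(v)]
            summary[f"turn_rate_per_min_{cls}"] = float(np.mean(per_min)) if per_min else None
        if landscape is not None:
            dist = distance_to_nearest_source(
                [a[0] for a in annotated], landscape.sources,
                snapshot_time=min(150.0, cfg["simulation"]["duration"] - 1.0))
            summary["distance_snapshot_cm"] = float(np.nanmean(dist["snapshot"]))
        report["cohorts"][block["name"]] = summary

        if genotype == "chrimson" and flashes is not None:
            import pandas as pd

            tables = [detect_flash_stops(a[3], flashes) for a in annotated]
            trials = pd.concat(tables, ignore_index=True)
            running = trials[trials["running_at_onset"]]
            sp = stop_probability(running["stopped"], level=cfg["stats"]["level"])
            report["flash"] = {
                "n_trials": int(sp["n"]),
                "stop_probability": sp["proportion"],
                "ci_lower": sp["lower"],
                "ci_upper": sp["upper"],
                "median_latency_s": float(np.nanmedian(trials["latency"]))
                if trials["stopped"].any() else None,
                "mean_stop_duration_s": float(np.nanmean(trials["duration"]))
                if trials["stopped"].any() else None,
            }
            if out_dir is not None:
                trials.to_csv(out_dir / "flash_trials.csv", index=False)

    # genotype contrast on down-gradient turn rates
    names = list(report["cohorts"])
    if landscape is not None and "wildtype" in names and "pdm_silenced" in names:
        wt = report["cohorts"]["wildtype"]
        sil = report["cohorts"]["pdm_silenced"]
        report["genotype_contrast"] = {
            "down_rate_wildtype": wt.get("turn_rate_per_min_DOWN"),
            "down_rate_silenced": sil.get("turn_rate_per_min_DOWN"),
            "snapshot_wildtype_cm": wt.get("distance_snapshot_cm"),
            "snapshot_silenced_cm": sil.get("distance_snapshot_cm"),
        }

    if cfg["waves"].get("enabled", True):
        wcfg = cfg["waves"]
        # 20-s flashes so the 20-s before/during counting windows coincide
        # with the stimulation period
        wave_flashes = FlashSchedule.periodic(n=int(wcfg["n_flashes"]), duration=20.0,
                                              gap=22.0, first_onset=22.0)
        traces, truth = generate_segment_traces(
            flashes=wave_flashes, rule=wcfg["rule"], noise_sd=wcfg["noise_sd"],
            wave_period=wcfg["wave_period"], wave_speed=wcfg["wave_speed"],
            seed=int(cfg["simulation"]["seed"]) + 7)
        waves = detect_segmental_waves(traces)
        outcomes = [
            classify_flash_outcome(waves, float(o), float(d), flash_id=k)
            for k, (o, d) in enumerate(zip(wave_flashes.onsets, wave_flashes.durations))
        ]
        counts = [count_waves(waves, float(o)) for o in wave_flashes.onsets]
        report["waves"] = {
            "n_waves_detected": len(waves),
            "n_complete": sum(1 for w in waves if w.complete),
            "outcomes": [o.category for o in outcomes],
            "true_outcomes": [o["category"] for o in truth["outcomes"]],
            "waves_before_mean": float(np.mean([c["n_before"] for c in counts])),
            "waves_during_mean": float(np.mean([c["n_during"] for c in counts])),
        }
        # proportion of flashes with any complete wave, before vs during
        k_before = sum(1 for c in counts if c["n_before"] > 0)
        k_during = sum(1 for c in counts if c["n_during"] > 0)
        zt = two_proportion_ztest(k_during, len(counts), k_before, len(counts))
        report["waves"]["suppression_ztest_p"] = zt["p_two_sided"]

    if cfg["dff"].get("enabled", True):
        dcfg = cfg["dff"]
        series, truth = generate_roi_traces(
            response_onsets=(10.0, 30.0, 50.0), noise_sd=2.0,
            seed=int(cfg["simulation"]["seed"]) + 11)
        d = dff(series, mode=dcfg["mode"], window=dcfg["window"])
        pk = peak_response(d, window=dcfg["response_window"])
        report["calcium"] = {
            "n_epochs": pk["n"],
            "mean_peak_dff": pk["mean"],
            "median_peak_dff": pk["median"],
            "true_peak_dff": truth["peak_dff"],
        }

    report = _round_floats(report)
    if out_dir is not None:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str) + "\n")
    return report
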