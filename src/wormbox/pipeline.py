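"""End-to-end demo pipeline: simulate the three scenarios, run every
analysis stage on the simulated observables, and write machine-readable
reports. Each stage consumes only the simulator's outputs or files written
by earlier stages."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aging_metrics, behavior_states, detect_eval, egg_analysis, kinematics
from .boxio import write_detections_csv
from .synthetic_data import (
    ScenarioConfig,
    bayes_accuracy,
    simulate_aging_cohort,
    simulate_detections,
    simulate_eggs,
    simulate_trajectory,
)

__all__ = ["RunConfig", "run_demo"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for a full pipeline run.

    Defaults are the working thresholds of the analyses: worm detections are
    trusted at confidence 0.5 and matched at IoU 0.5; eggs, being small and
    easily occluded, are counted at confidence 0.01 and matched at IoU 0.3;
    behavioral states are split at 90 deg/min angular velocity computed at
    1-minute sampling; moving averages span 10 samples.
    """

    worm_confidence: float = 0.5
    egg_confidence: float = 0.01
    worm_iou: float = 0.5
    egg_iou: float = 0.3
    angular_split_deg_per_min: float = 90.0
    sampling_interval_min: float = 1.0
    smoothing_window: int = 10
    seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("worm_confidence", self.worm_confidence, 0.0, 1.0),
            ("egg_confidence", self.egg_confidence, 0.0, 1.0),
            ("worm_iou", self.worm_iou, 1e-9, 1.0),
            ("egg_iou", self.egg_iou, 1e-9, 1.0),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.angular_split_deg_per_min <= 0 or self.sampling_interval_min <= 0:
            raise ValueError("angular split and sampling interval must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "scenario"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def run_demo(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full simulate-and-analyze demonstration.

    Writes ``summary.json`` plus per-stage artifacts under ``out_dir`` and
    returns the summary dict. Deterministic given the config (incl. seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.scenario
    cal = sc.calibration
    summary: dict = {"seed": config.seed, "parameters": _params_dict(config)}

    # --- developmental trajectory: detection quality + kinematics + states
    log.info("stage=trajectory seed=%d duration_min=%s", config.seed, sc.duration_min)
    track_true, truth_states = simulate_trajectory(sc, seed=config.seed)
    frames = simulate_detections(track_true, sc, seed=config.seed)
    write_detections_csv(frames, out / "detections.csv")

    report = detect_eval.evaluate(
        frames, "worm", config.worm_confidence, config.worm_iou
    )
    summary["detection"] = report.to_dict()
    summary["detection"].pop("pr_points")

    track = kinematics.assemble_track(
        frames, "worm", config.worm_confidence, policy="nearest_to_previous"
    )
    track.to_csv(out / "track.csv")
    disp = kinematics.displacement_series(track, config.sampling_interval_min, cal)
    _, fold = kinematics.box_growth(track, config.smoothing_window)
    summary["kinematics"] = {
        "n_track_samples": len(track),
        "mean_velocity_mm_per_min": float(disp["velocity_mm_per_min"].mean()),
        "box_area_fold_change": fold,
    }

    ang = behavior_states.angular_velocity(track, config.sampling_interval_min, cal)
    states = behavior_states.classify(
        ang, behavior_states.SplitRule(angular_threshold=config.angular_split_deg_per_min)
    )
    acc, confusion = behavior_states.state_accuracy(states, truth_states)
    summary["behavior_states"] = {
        "accuracy_vs_truth": acc,
        "bayes_accuracy": bayes_accuracy(sc.states),
        "confusion": confusion.to_dict(),
        "roaming_fraction": float((states == behavior_states.ROAMING).mean()),
    }

    # --- egg-laying scenario
    log.info("stage=eggs rate=%s p_on=%s", sc.eggs.rate_eggs_per_hr, sc.eggs.p_on)
    eggs = simulate_eggs(sc, seed=config.seed)
    merge_radius = egg_analysis.EGG_DIAMETER_MM / cal.mm_per_pixel
    counts = {}
    for key, fr_set in (("t1", eggs.frames_t1), ("t2", eggs.frames_t2)):
        _, obs = egg_analysis.count_eggs(fr_set, config.egg_confidence, layout=eggs.layout)
        merged = egg_analysis.dedup_tiles(obs, merge_radius)
        counts[key] = merged
    t1, t2 = sc.eggs.snapshot_times_hr
    rate1, rate2 = egg_analysis.egg_rates(len(counts["t1"]), len(counts["t2"]), t1, t2)
    flagged = egg_analysis.assign_lawn(counts["t2"], eggs.lawn)
    n_on = sum(1 for o in flagged if o.on_lawn)
    pref = egg_analysis.preference_score(n_on, len(flagged) - n_on)
    summary["eggs"] = {
        "count_t1": len(counts["t1"]),
        "count_t2": len(counts["t2"]),
        "true_count_t1": int((eggs.truth.time_hr <= t1).sum()),
        "true_count_t2": int((eggs.truth.time_hr <= t2).sum()),
        "rate1_eggs_per_hr": rate1,
        "rate2_eggs_per_hr": rate2,
        "preference_score": pref,
        "expected_preference": 2 * sc.eggs.p_on - 1,
    }

    # --- aging scenario
    log.info("stage=aging n=%d per food level", sc.aging.n_individuals)
    aging = simulate_aging_cohort(sc, seed=config.seed)
    scores = [
        aging_metrics.VideoScore(
            v.individual_id, v.age, v.food_level,
            aging_metrics.movement_score(v.first_box, v.last_box),
            aging_metrics.pixel_change(v.mask_first, v.mask_last),
        )
        for v in aging.videos
    ]
    levels = sorted(sc.aging.midpoints)
    summaries = {lvl: aging_metrics.score_cohort(scores, lvl) for lvl in levels}
    summary["aging"] = {lvl: s.to_dict() for lvl, s in summaries.items()}
    if len(levels) == 2:
        summary["aging"]["food_level_comparison"] = aging_metrics.compare_food_levels(
            summaries[levels[0]], summaries[levels[1]]
        )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    log.info("demo complete: %s", out / "summary.json")
    return summary


def _params_dict(config: RunConfig) -> dict:
    return {
        "worm_confidence": config.worm_confidence,
        "egg_confidence": config.egg_confidence,
        "worm_iou": config.worm_iou,
        "egg_iou": config.egg_iou,
        "angular_split_deg_per_min": config.angular_split_deg_per_min,
        "sampling_interval_min": config.sampling_interval_min,
        "smoothing_window": config.smoothing_window,
    }


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
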