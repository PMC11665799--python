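"""End-to-end orchestration: simulate -> filter -> metrics -> stats -> eval.

Batch (post-trial) processing only: a run reads or simulates a study,
computes the per-trial metric table, both t-test experiments and the
learning curves, optionally evaluates detector quality against ground
truth, and writes everything to an output directory together with a run
log carrying the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io as tio
from .core import EXPERT, NOVICE, TrialDescriptor, TrialRecording, ValidationError
from .detector_eval import APResult, make_leave_two_user_out_folds, map50
from .metrics import metrics_table
from .simulate import SimulationConfig, simulate_study, write_study
from .stats import (
    TTestResult,
    compare_groups,
    first_vs_last,
    learning_curve_table,
    learning_curves,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(slots=True)
class RunConfig:
    """Inputs and outputs of one pipeline run."""

    outdir: Union[str, Path]
    seed: int = 0
    manifest: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    fmt: str = "coco"
    iou_threshold: float = 0.5
    detector_eval: bool = True
    welch: bool = False


def load_trial(descriptor: TrialDescriptor) -> TrialRecording:
    """Materialize one trial from its manifest row (COCO or YOLO layout)."""

    def read(path: str, camera_id: str):
        p = Path(path)
        if p.is_dir():
            return tio.read_yolo_frames(
                p, frame_rate=descriptor.frame_rate, camera_id=camera_id
            )
        return tio.read_coco_detections(
            p, camera_id=camera_id, frame_rate=descriptor.frame_rate
        )

    streams = {
        "left": read(descriptor.left_path, "left"),
        "right": read(descriptor.right_path, "right"),
    }
    ground_truth = None
    if descriptor.left_truth_path and descriptor.right_truth_path:
        ground_truth = {
            "left": read(descriptor.left_truth_path, "left"),
            "right": read(descriptor.right_truth_path, "right"),
        }
    return TrialRecording(
        participant_id=descriptor.participant_id,
        group=descriptor.group,
        trial_index=descriptor.trial_index,
        streams=streams,
        ground_truth=ground_truth,
    )


def load_trials(manifest_path: Union[str, Path]) -> list[TrialRecording]:
    descriptors = tio.load_trial_manifest(manifest_path)
    if not descriptors:
        raise PipelineError("metrics stage: no trials in manifest")
    return [load_trial(d) for d in descriptors]


def stats_report(metric_table: pd.DataFrame, welch: bool = False) -> dict:
    """Both experiments plus learning curves as one JSON-serializable dict."""
    report = {
        "novices_vs_experts": [r.as_dict() for r in compare_groups(metric_table, welch=welch)],
        "first_vs_last": {
            group: [r.as_dict() for r in first_vs_last(metric_table, group)]
            for group in (NOVICE, EXPERT)
        },
        "learning_curves": [c.as_dict() for c in learning_curves(metric_table)],
    }
    return report


def evaluate_study_detections(
    trials: Sequence[TrialRecording],
    iou_threshold: float = 0.5,
    participants: Optional[Sequence[str]] = None,
) -> APResult:
    """mAP50 of the trials' detections against their ground-truth streams.

    Optionally restricted to a participant subset (e.g. one fold's test
    users). Trials without ground truth are an error.
    """
    pairs = []
    for trial in trials:
        if participants is not None and trial.participant_id not in participants:
            continue
        if trial.ground_truth is None:
            raise PipelineError(
                f"detector-eval stage: trial {trial.participant_id}/{trial.trial_index} "
                "has no ground-truth streams"
            )
        for camera_id, stream in trial.streams.items():
            pairs.append((stream, trial.ground_truth[camera_id]))
    if not pairs:
        raise PipelineError("detector-eval stage: no trials with ground truth")
    return map50(pairs, iou_threshold=iou_threshold)


def format_p(p: float) -> str:
    """Render a p-value the way the statistics report prints it.

    Two decimals at p >= 0.01, three decimals down to 0.002, scientific
    with two significant digits below that (e.g. ``1.8e-3``).
    """
    if math.isnan(p):
        return "nan"
    if p >= 0.01:
        return f"{p:.2f}"
    if p >= 0.002:
        return f"{p:.3f}"
    return f"{p:.1e}".replace("e-0", "e-")


def summarize_report(report: dict) -> str:
    """Human-readable per-metric lines: ``metric: t = x.xx, p = y (df = n)``."""
    lines = []
    for res in report.get("novices_vs_experts", []):
        lines.append(_format_result_line("novices vs experts", res))
    for group, results in report.get("first_vs_last", {}).items():
        for res in results:
            lines.append(_format_result_line(f"first vs last ({group})", res))
    return "\n".join(lines)


def _format_result_line(experiment: str, res: dict) -> str:
    return (
        f"{experiment} — {res['metric']}: t = {res['t']:.2f}, "
        f"p = {format_p(res['p'])} (df = {res['df']})"
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages and write the report files.

    Returns a mapping from artifact name to path. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    manifest = config.manifest
    trials: Optional[list[TrialRecording]] = None
    if config.simulation is not None:
        try:
            study = simulate_study(config.simulation, config.seed)
            manifest = write_study(study, outdir / "data", fmt=config.fmt)
            trials = [t.detected for t in study]
        except Exception as exc:
            raise PipelineError(f"simulate stage: {exc}") from exc
        artifacts["manifest"] = Path(manifest)
    elif manifest is None:
        raise PipelineError("simulate stage: neither a manifest nor a simulation config given")

    try:
        if trials is None:
            trials = load_trials(manifest)
        if not trials:
            raise ValidationError("no trials")
        table = metrics_table(trials)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"metrics stage: {exc}") from exc
    metrics_path = outdir / "metrics.csv"
    tio.write_metrics_table(table, metrics_path)
    artifacts["metrics"] = metrics_path

    try:
        report = stats_report(table, welch=config.welch)
    except Exception as exc:
        raise PipelineError(f"stats stage: {exc}") from exc
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(report, indent=2))
    artifacts["stats"] = stats_path

    curves_path = outdir / "learning_curves.csv"
    learning_curve_table(learning_curves(table)).to_csv(curves_path, index=False)
    artifacts["learning_curves"] = curves_path

    summary_path = outdir / "summary.txt"
    summary_path.write_text(summarize_report(report) + "\n")
    artifacts["summary"] = summary_path

    if config.detector_eval and any(t.ground_truth is not None for t in trials):
        try:
            ap = evaluate_study_detections(
                [t for t in trials if t.ground_truth is not None],
                iou_threshold=config.iou_threshold,
            )
        except Exception as exc:
            raise PipelineError(f"detector-eval stage: {exc}") from exc
        eval_path = outdir / "detector_eval.json"
        eval_path.write_text(json.dumps(ap.as_dict(), indent=2))
        artifacts["detector_eval"] = eval_path

    novices = sorted({t.participant_id for t in trials if t.group == NOVICE})
    experts = sorted({t.participant_id for t in trials if t.group == EXPERT})
    if len(novices) == len(experts) and len(novices) >= 2:
        folds = make_leave_two_user_out_folds(novices, experts)
        folds_path = outdir / "folds.json"
        folds_path.write_text(json.dumps([f.as_dict() for f in folds], indent=2))
        artifacts["folds"] = folds_path

    log = {
        "seed": config.seed,
        "iou_threshold": config.iou_threshold,
        "config_hash": _config_hash(config),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    artifacts["run_log"] = log_path
    return artifacts


def _config_hash(config: RunConfig) -> str:
    payload = {
        "seed": config.seed,
        "manifest": str(config.manifest) if config.manifest else None,
        "simulation": config.simulation.to_dict() if config.simulation else None,
        "fmt": config.fmt,
        "iou_threshold": config.iou_threshold,
        "welch": config.welch,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
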