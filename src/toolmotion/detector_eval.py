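"""Detector-quality evaluation: IoU, greedy matching, AP and mAP50.

Average precision follows the PASCAL VOC lineage: detections are pooled
over all frames of the evaluation split, ranked by confidence, matched
greedily (highest IoU first, each ground-truth box used at most once), and
AP is the area under the precision envelope of the precision–recall curve
(all-point interpolation by default; the legacy 11-point variant is an
option). mAP50 is the unweighted mean of the per-class APs at an IoU
threshold of 0.5. Evaluation always uses ALL predicted boxes — best-box
filtering is a metric-side simplification, not an evaluation rule.

Also provides the leave-two-user-out fold planner: each fold reserves one
novice and one expert for testing and the cyclically next pair for
validation, until every participant has been tested once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    TOOL_CLASSES,
    BoundingBox,
    CameraStream,
    ValidationError,
)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes with continuous-coordinate areas."""
    if a.area <= 0 or b.area <= 0:
        raise ValidationError("IoU of a degenerate (zero-area) box is undefined")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(slots=True)
class MatchResult:
    """Per-prediction TP/FP flags with confidences, for one class.

    ``n_gt`` counts ground-truth boxes; unmatched ground truth is a miss.
    Results from many frames are accumulated with :meth:`extend` before the
    PR curve is built.
    """

    confidences: list[float] = field(default_factory=list)
    is_tp: list[bool] = field(default_factory=list)
    n_gt: int = 0

    def extend(self, other: "MatchResult") -> None:
        self.confidences.extend(other.confidences)
        self.is_tp.extend(other.is_tp)
        self.n_gt += other.n_gt


def match_detections(
    predictions: Sequence[BoundingBox],
    ground_truth: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match one frame's predictions of one class to ground truth.

    Predictions are processed in descending confidence (stable on ties);
    each is a true positive if its best-IoU unmatched ground-truth box
    reaches the threshold, otherwise a false positive.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValidationError(f"IoU threshold {iou_threshold} outside (0, 1]")
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i].confidence)
    matched: set[int] = set()
    result = MatchResult(n_gt=len(ground_truth))
    confs = [0.0] * len(predictions)
    flags = [False] * len(predictions)
    for rank, i in enumerate(order):
        pred = predictions[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truth):
            if j in matched:
                continue
            overlap = iou(pred, gt)
            if overlap > best_iou:
                best_iou, best_j = overlap, j
        hit = best_iou >= iou_threshold and best_j >= 0
        if hit:
            matched.add(best_j)
        confs[rank] = pred.confidence
        flags[rank] = hit
    result.confidences = confs
    result.is_tp = flags
    return result


def average_precision(
    result: MatchResult, interpolation: str = "all_point"
) -> Optional[float]:
    """Area under the precision envelope of the PR curve.

    Returns ``None`` (class skipped) when there is neither ground truth nor
    any prediction; 0.0 when predictions exist without ground truth. The
    value is invariant under strictly increasing transformations of the
    confidences because only the ranking enters.
    """
    if result.n_gt == 0:
        return 0.0 if result.confidences else None
    if not result.confidences:
        return 0.0
    conf = np.asarray(result.confidences, dtype=float)
    tp = np.asarray(result.is_tp, dtype=float)
    order = np.argsort(-conf, kind="stable")
    tp = tp[order]
    fp = 1.0 - tp
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(fp)
    recall = cum_tp / result.n_gt
    precision = cum_tp / (cum_tp + cum_fp)

    if interpolation == "all_point":
        # VOC 2010+ / COCO style: integrate the monotone precision envelope
        r = np.concatenate(([0.0], recall, [1.0]))
        p = np.concatenate(([0.0], precision, [0.0]))
        p = np.maximum.accumulate(p[::-1])[::-1]
        jumps = np.nonzero(r[1:] != r[:-1])[0]
        return float(np.sum((r[jumps + 1] - r[jumps]) * p[jumps + 1]))
    if interpolation == "11_point":
        levels = np.linspace(0.0, 1.0, 11)
        precisions = [
            float(precision[recall >= level].max()) if np.any(recall >= level) else 0.0
            for level in levels
        ]
        return float(np.mean(precisions))
    raise ValidationError(f"unknown interpolation {interpolation!r}")


@dataclass(slots=True)
class APResult:
    """Per-class average precision and its unweighted mean (mAP)."""

    per_class: dict[str, float]
    mean_ap: float
    iou_threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "per_class": dict(self.per_class),
            "mAP": self.mean_ap,
        }


def _stream_pairs(
    predicted: CameraStream | Iterable[tuple[CameraStream, CameraStream]],
    truth: Optional[CameraStream],
) -> list[tuple[CameraStream, CameraStream]]:
    if truth is not None:
        return [(predicted, truth)]  # type: ignore[list-item]
    return list(predicted)  # type: ignore[arg-type]


def map50(
    predicted: CameraStream | Iterable[tuple[CameraStream, CameraStream]],
    truth: Optional[CameraStream] = None,
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> APResult:
    """Mean average precision over classes at a fixed IoU threshold.

    Accepts a single ``(predicted, truth)`` stream pair or an iterable of
    pairs (e.g. both cameras of many trials); detections are pooled over
    all frames before ranking. Frames are aligned by frame index within
    each pair. Classes never present in the ground truth are skipped.
    """
    pairs = _stream_pairs(predicted, truth)
    results: dict[str, MatchResult] = {tool: MatchResult() for tool in TOOL_CLASSES}
    total_gt = 0
    for pred_stream, truth_stream in pairs:
        truth_frames = {f.frame_index: f for f in truth_stream.frames}
        pred_frames = {f.frame_index: f for f in pred_stream.frames}
        for idx in sorted(set(truth_frames) | set(pred_frames)):
            gt_boxes = truth_frames[idx].boxes if idx in truth_frames else []
            pr_boxes = pred_frames[idx].boxes if idx in pred_frames else []
            total_gt += len(gt_boxes)
            for tool in TOOL_CLASSES:
                results[tool].extend(
                    match_detections(
                        [b for b in pr_boxes if b.label == tool],
                        [b for b in gt_boxes if b.label == tool],
                        iou_threshold,
                    )
                )
    if total_gt == 0:
        raise ValidationError("no ground-truth boxes in any evaluation frame")

    per_class: dict[str, float] = {}
    for tool in TOOL_CLASSES:
        ap = average_precision(results[tool], interpolation=interpolation)
        if ap is not None:
            per_class[tool] = ap
    mean_ap = float(np.mean(list(per_class.values())))
    return APResult(per_class=per_class, mean_ap=mean_ap, iou_threshold=iou_threshold)


# ---------------------------------------------------------------------------
# Grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class FoldPlan:
    """One leave-two-user-out fold: test, validation and train participants."""

    fold_index: int
    test: tuple[str, str]
    validation: tuple[str, str]
    train: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "test": list(self.test),
            "validation": list(self.validation),
            "train": list(self.train),
        }


def make_leave_two_user_out_folds(
    novices: Sequence[str], experts: Sequence[str]
) -> list[FoldPlan]:
    """Plan folds reserving one novice + one expert for test per fold.

    The i-th fold tests the i-th novice/expert pair and validates on the
    cyclically next pair; everyone else trains. Each participant appears in
    the test set exactly once across folds.
    """
    if len(novices) != len(experts):
        raise ValidationError(
            f"group sizes differ ({len(novices)} novices, {len(experts)} experts)"
        )
    if len(set(novices) | set(experts)) != len(novices) + len(experts):
        raise ValidationError("participant ids must be unique across groups")
    n = len(novices)
    if n < 2:
        raise ValidationError(
            "need at least two participants per group so validation does not overlap test"
        )
    everyone = set(novices) | set(experts)
    folds = []
    for i in range(n):
        j = (i + 1) % n
        test = (novices[i], experts[i])
        validation = (novices[j], experts[j])
        train = tuple(
            p for p in list(novices) + list(experts) if p not in {*test, *validation}
        )
        folds.append(FoldPlan(fold_index=i, test=test, validation=validation, train=train))
    return folds
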