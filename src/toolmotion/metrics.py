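"""Per-trial motion-efficiency metrics from bounding-box streams.

Seven numbers summarize one trial: the total procedure time, per-tool usage
times (visible-frame count over the frame rate), and per-tool center and
corner path lengths in pixels. Path lengths bridge visibility gaps: the
distance is taken to the next frame in which the tool is visible, however
far away, so dropping invisible frames never changes the result.

When a trial was recorded by two cameras, each metric is computed per
camera and the per-trial value is the maximum over the two views; the
total procedure time is shared by construction (synchronized streams).

Frames may carry several boxes of one class straight from a detector;
metrics are always computed on best-box-filtered streams (highest
confidence per class per frame, earliest listed on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    METRIC_NAMES,
    NEEDLE,
    PROBE,
    TOOL_CLASSES,
    BoundingBox,
    CameraStream,
    FrameDetections,
    MetricSet,
    TrialRecording,
    ValidationError,
)


@dataclass(slots=True)
class VisibilitySeries:
    """Frames in which one tool is predicted visible, one box per frame."""

    tool: str
    entries: list[tuple[int, BoundingBox]]

    def __len__(self) -> int:
        return len(self.entries)

    def coordinates(self) -> np.ndarray:
        """(n, 4) array of box extents in entry order."""
        return np.array(
            [(b.x_min, b.y_min, b.x_max, b.y_max) for _, b in self.entries],
            dtype=float,
        ).reshape(len(self.entries), 4)


def select_best_boxes(frame: FrameDetections) -> FrameDetections:
    """Keep only the highest-confidence box per class.

    Ties keep the earliest-listed box, so results are deterministic for any
    input ordering contract honoured by the parsers.
    """
    best: dict[str, BoundingBox] = {}
    for box in frame.boxes:
        incumbent = best.get(box.label)
        if incumbent is None or box.confidence > incumbent.confidence:
            best[box.label] = box
    # preserve first-appearance order of classes
    kept, seen = [], set()
    for box in frame.boxes:
        if box.label not in seen:
            kept.append(best[box.label])
            seen.add(box.label)
    return FrameDetections(frame_index=frame.frame_index, boxes=kept)


def filter_stream(stream: CameraStream) -> CameraStream:
    """Best-box-filter every frame of a stream."""
    return CameraStream(
        camera_id=stream.camera_id,
        frames=[select_best_boxes(f) for f in stream.frames],
        frame_rate=stream.frame_rate,
        width=stream.width,
        height=stream.height,
    )


def visibility_series(stream: CameraStream, tool: str) -> VisibilitySeries:
    """Extract the frames where ``tool`` is predicted visible.

    Applies best-box filtering internally, so multi-box frames are safe.
    """
    if tool not in TOOL_CLASSES:
        raise ValidationError(f"unknown tool {tool!r}; expected one of {TOOL_CLASSES}")
    entries: list[tuple[int, BoundingBox]] = []
    for frame in stream.frames:
        best: BoundingBox | None = None
        for box in frame.boxes:
            if box.label == tool and (best is None or box.confidence > best.confidence):
                best = box
        if best is not None:
            entries.append((frame.frame_index, best))
    return VisibilitySeries(tool=tool, entries=entries)


def total_procedure_time(trial: TrialRecording) -> float:
    """Recording length in seconds: shared frame count / nominal frame rate."""
    if trial.n_frames == 0:
        return 0.0
    return trial.n_frames / trial.frame_rate


def usage_time(stream: CameraStream, tool: str) -> float:
    """Seconds during which the tool is predicted visible in this view."""
    if stream.frame_rate <= 0:
        raise ValidationError("frame_rate must be > 0")
    return len(visibility_series(stream, tool)) / stream.frame_rate


def center_path_length(series: VisibilitySeries) -> float:
    """Cumulative Euclidean distance between consecutive box centers (px)."""
    if len(series) < 2:
        return 0.0
    coords = series.coordinates()
    centers = np.column_stack(
        ((coords[:, 0] + coords[:, 2]) / 2.0, (coords[:, 1] + coords[:, 3]) / 2.0)
    )
    steps = np.diff(centers, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def corner_path_length(series: VisibilitySeries) -> float:
    """Cumulative sum of the four corner-to-corresponding-corner distances.

    Corners are matched in fixed TL, TR, BR, BL order between consecutive
    visible frames; sensitive to box-size change as well as translation.
    """
    if len(series) < 2:
        return 0.0
    coords = series.coordinates()
    x0, y0, x1, y1 = coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3]
    # corners stacked as (n, 4, 2): TL, TR, BR, BL
    corners = np.stack(
        (
            np.column_stack((x0, y0)),
            np.column_stack((x1, y0)),
            np.column_stack((x1, y1)),
            np.column_stack((x0, y1)),
        ),
        axis=1,
    )
    steps = np.diff(corners, axis=0)
    return float(np.hypot(steps[..., 0], steps[..., 1]).sum())


def stream_metrics(stream: CameraStream) -> dict[str, float]:
    """Usage times and path lengths for one camera view."""
    values: dict[str, float] = {}
    for tool, suffix in ((PROBE, "probe"), (NEEDLE, "needle")):
        series = visibility_series(stream, tool)
        values[f"usage_time_{suffix}"] = len(series) / stream.frame_rate
        values[f"center_path_{suffix}"] = center_path_length(series)
        values[f"corner_path_{suffix}"] = corner_path_length(series)
    return values


def trial_metrics(trial: TrialRecording) -> MetricSet:
    """Compute the seven per-trial metrics, maximized over camera views."""
    per_camera = [stream_metrics(s) for s in trial.streams.values()]
    merged = {
        name: max(values[name] for values in per_camera)
        for name in per_camera[0]
    }
    return MetricSet(total_procedure_time=total_procedure_time(trial), **merged)


def metrics_table(
    trials: Iterable[TrialRecording],
) -> pd.DataFrame:
    """One row per trial: participant id, group, trial index, seven metrics."""
    rows = []
    for trial in trials:
        row = {
            "participant_id": trial.participant_id,
            "group": trial.group,
            "trial_index": trial.trial_index,
        }
        row.update(trial_metrics(trial).as_dict())
        rows.append(row)
    columns = ["participant_id", "group", "trial_index", *METRIC_NAMES]
    return pd.DataFrame(rows, columns=columns)
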