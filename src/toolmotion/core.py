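"""Domain containers for per-frame tool detections.

The package analyses procedures recorded by two synchronized webcams. An
object detector emits axis-aligned bounding boxes for two tool classes
(an ultrasound probe and a nephrostomy needle) on every frame; everything
downstream — motion metrics, group statistics, detector evaluation — works
on these containers.

Coordinates are continuous pixels in corner form ``(x_min, y_min, x_max,
y_max)`` with the origin at the top-left, x rightward, y downward. Areas
use the continuous product ``(x_max - x_min) * (y_max - y_min)`` with no
+1 correction, matching COCO arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

PROBE = "ultrasound_probe"
NEEDLE = "needle"
TOOL_CLASSES: tuple[str, str] = (PROBE, NEEDLE)

NOVICE = "novice"
EXPERT = "expert"
GROUPS: tuple[str, str] = (NOVICE, EXPERT)

CAMERA_IDS: tuple[str, str] = ("left", "right")


class ValidationError(ValueError):
    """Raised when an input record violates a container invariant."""


@dataclass(slots=True)
class BoundingBox:
    """One axis-aligned detection in continuous pixel coordinates.

    Instances are treated as immutable by the whole package; fields are
    validated on construction only.
    """

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValidationError(
                f"degenerate box extents ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}): min must be < max on both axes"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def corners(self) -> tuple[tuple[float, float], ...]:
        """Corners in fixed TL, TR, BR, BL order (axis-aligned boxes only)."""
        return (
            (self.x_min, self.y_min),
            (self.x_max, self.y_min),
            (self.x_max, self.y_max),
            (self.x_min, self.y_max),
        )


@dataclass(slots=True)
class FrameDetections:
    """All detections on one frame; may hold several boxes per class."""

    frame_index: int
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame index {self.frame_index}")


@dataclass(slots=True)
class CameraStream:
    """Ordered per-frame detections for one camera view.

    Frames are ordered by strictly increasing ``frame_index``; a frame with
    no detections is an empty :class:`FrameDetections`, never a skipped
    index, so visibility-time denominators stay well defined.
    """

    camera_id: str
    frames: list[FrameDetections]
    frame_rate: float
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        indices = [f.frame_index for f in self.frames]
        if any(b >= a for a, b in zip(indices[1:], indices)):
            raise ValidationError(
                f"frame indices of camera {self.camera_id!r} are not strictly increasing"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Recording length in seconds (frame count / nominal frame rate)."""
        return self.n_frames / self.frame_rate

    def __iter__(self) -> Iterator[FrameDetections]:
        return iter(self.frames)


@dataclass(slots=True)
class TrialRecording:
    """One participant's trial: one or two synchronized camera streams.

    ``ground_truth`` optionally carries noise-free annotation streams keyed
    by the same camera ids, for detector evaluation.
    """

    participant_id: str
    group: str
    trial_index: int
    streams: dict[str, CameraStream]
    ground_truth: Optional[dict[str, CameraStream]] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based and must be >= 1")
        if not self.streams:
            raise ValidationError("trial must contain at least one camera stream")
        counts = {s.n_frames for s in self.streams.values()}
        rates = {s.frame_rate for s in self.streams.values()}
        if len(counts) > 1 or len(rates) > 1:
            raise ValidationError(
                f"streams of trial {self.participant_id}/{self.trial_index} are not "
                f"synchronized (frame counts {sorted(counts)}, rates {sorted(rates)})"
            )

    @property
    def n_frames(self) -> int:
        return next(iter(self.streams.values())).n_frames

    @property
    def frame_rate(self) -> float:
        return next(iter(self.streams.values())).frame_rate


#: Canonical column order of the seven per-trial skill metrics.
METRIC_NAMES: tuple[str, ...] = (
    "total_procedure_time",
    "usage_time_probe",
    "usage_time_needle",
    "center_path_probe",
    "center_path_needle",
    "corner_path_probe",
    "corner_path_needle",
)


@dataclass(slots=True)
class MetricSet:
    """The seven per-trial skill metrics.

    Times are in seconds, path lengths in pixels. One time, two per-tool
    usage times and four per-tool path lengths (center and corner variants).
    """

    total_procedure_time: float
    usage_time_probe: float
    usage_time_needle: float
    center_path_probe: float
    center_path_needle: float
    corner_path_probe: float
    corner_path_needle: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(slots=True)
class TrialDescriptor:
    """Manifest row locating one trial's detection files."""

    participant_id: str
    group: str
    trial_index: int
    left_path: str
    right_path: str
    frame_rate: float
    left_truth_path: Optional[str] = None
    right_truth_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
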