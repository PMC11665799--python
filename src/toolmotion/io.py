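"""Reading and writing detection records, manifests and metric tables.

Two interchange dialects are supported for per-camera detection streams:

* COCO-style JSON — one file per camera with ``images`` (frame index in an
  explicit ``frame_index`` field or encoded in the file name),
  ``categories``, and ``annotations`` carrying ``bbox`` as ``[x, y, w, h]``
  plus a ``score``.
* YOLO-style text — one file per frame, each line
  ``class cx cy w h [confidence]`` normalized to [0, 1].

Both round-trip losslessly through :class:`~toolmotion.core.CameraStream`.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    GROUPS,
    METRIC_NAMES,
    NEEDLE,
    PROBE,
    BoundingBox,
    CameraStream,
    FrameDetections,
    MetricSet,
    TrialDescriptor,
    ValidationError,
)

PathLike = Union[str, Path]

#: Default class-id table shared by both dialects (COCO ids are 1-based).
DEFAULT_COCO_CATEGORIES: dict[int, str] = {1: PROBE, 2: NEEDLE}
DEFAULT_YOLO_CLASS_MAP: dict[int, str] = {0: PROBE, 1: NEEDLE}

_FRAME_NUMBER = re.compile(r"(\d+)")


class ParseError(ValueError):
    """Raised when a detection file cannot be parsed."""


def _frame_index_from_name(name: str) -> int:
    matches = _FRAME_NUMBER.findall(Path(name).stem)
    if not matches:
        raise ParseError(f"cannot infer frame index from file name {name!r}")
    return int(matches[-1])


# ---------------------------------------------------------------------------
# COCO-style JSON
# ---------------------------------------------------------------------------

def read_coco_detections(
    path: PathLike,
    camera_id: str,
    frame_rate: Optional[float] = None,
    width: Optional[int] = None,
    height: Optional[int] = None,
) -> CameraStream:
    """Load one camera's detections from a COCO-style JSON file.

    Frames are listed even when they carry no boxes. Geometry and frame
    rate are taken from the file's ``info`` block when present; explicit
    arguments override it.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON in {path}: {exc}") from exc

    info = doc.get("info", {})
    frame_rate = frame_rate if frame_rate is not None else info.get("frame_rate")
    if frame_rate is None:
        raise ParseError(f"{path}: no frame_rate in info block and none supplied")
    width = width if width is not None else info.get("width", 640)
    height = height if height is not None else info.get("height", 480)

    categories = {c["id"]: c["name"] for c in doc.get("categories", [])}
    if not categories:
        categories = dict(DEFAULT_COCO_CATEGORIES)

    frames: dict[int, FrameDetections] = {}
    image_frame: dict[int, int] = {}
    for image in doc.get("images", []):
        idx = image.get("frame_index")
        if idx is None:
            idx = _frame_index_from_name(image.get("file_name", ""))
        image_frame[image["id"]] = idx
        frames[idx] = FrameDetections(frame_index=idx)

    for ann in doc.get("annotations", []):
        image_id = ann.get("image_id")
        if image_id not in image_frame:
            raise ParseError(f"{path}: annotation {ann.get('id')} references unknown image {image_id}")
        idx = image_frame[image_id]
        cat = ann.get("category_id")
        if cat not in categories:
            raise ParseError(
                f"{path}: annotation {ann.get('id')} has unknown category id {cat}; "
                f"known classes: {sorted(categories.items())}"
            )
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValidationError(
                f"{path}: non-positive box width/height {w}x{h} on frame {idx}"
            )
        frames[idx].boxes.append(
            BoundingBox(
                label=categories[cat],
                x_min=float(x),
                y_min=float(y),
                x_max=float(x) + float(w),
                y_max=float(y) + float(h),
                confidence=float(ann.get("score", 1.0)),
            )
        )

    ordered = [frames[idx] for idx in sorted(frames)]
    return CameraStream(
        camera_id=camera_id,
        frames=ordered,
        frame_rate=float(frame_rate),
        width=int(width),
        height=int(height),
    )


def write_coco_detections(stream: CameraStream, path: PathLike) -> None:
    """Write a stream as COCO-style JSON (inverse of :func:`read_coco_detections`)."""
    name_to_id = {name: cid for cid, name in DEFAULT_COCO_CATEGORIES.items()}
    extra = sorted(
        {b.label for f in stream.frames for b in f.boxes} - set(name_to_id)
    )
    for label in extra:
        name_to_id[label] = max(name_to_id.values(), default=0) + 1

    images, annotations = [], []
    ann_id = 1
    for image_id, frame in enumerate(stream.frames, start=1):
        images.append(
            {
                "id": image_id,
                "file_name": f"frame_{frame.frame_index:06d}.png",
                "frame_index": frame.frame_index,
                "width": stream.width,
                "height": stream.height,
            }
        )
        for box in frame.boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_id,
                    "category_id": name_to_id[box.label],
                    "bbox": [box.x_min, box.y_min, box.width, box.height],
                    "score": box.confidence,
                }
            )
            ann_id += 1

    doc = {
        "info": {
            "camera_id": stream.camera_id,
            "frame_rate": stream.frame_rate,
            "width": stream.width,
            "height": stream.height,
        },
        "categories": [
            {"id": cid, "name": name} for name, cid in sorted(name_to_id.items(), key=lambda kv: kv[1])
        ],
        "images": images,
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# YOLO-style per-frame text
# ---------------------------------------------------------------------------

def read_yolo_frames(
    directory: PathLike,
    class_map: Optional[Mapping[int, str]] = None,
    width: int = 640,
    height: int = 480,
    frame_rate: float = 10.0,
    camera_id: str = "left",
) -> CameraStream:
    """Load a directory of per-frame YOLO text files into a stream.

    Each line is ``class cx cy w h [confidence]`` with coordinates
    normalized to [0, 1]; a missing confidence defaults to 1.0. Frame order
    follows the numeric sort of the file names; an empty file is an empty
    frame.
    """
    class_map = dict(class_map) if class_map is not None else dict(DEFAULT_YOLO_CLASS_MAP)
    directory = Path(directory)
    files = sorted(directory.glob("*.txt"), key=lambda p: _frame_index_from_name(p.name))

    frames: list[FrameDetections] = []
    for file in files:
        idx = _frame_index_from_name(file.name)
        frame = FrameDetections(frame_index=idx)
        for lineno, line in enumerate(file.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ParseError(f"{file}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            cls = int(parts[0])
            if cls not in class_map:
                raise ParseError(
                    f"{file}:{lineno}: class index {cls} absent from class map "
                    f"{sorted(class_map.items())}"
                )
            cx, cy, w, h = map(float, parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
            for value, name in ((cx, "cx"), (cy, "cy"), (w, "w"), (h, "h")):
                if not 0.0 <= value <= 1.0:
                    raise ValidationError(
                        f"{file}:{lineno}: normalized {name}={value} outside [0, 1]"
                    )
            frame.boxes.append(
                BoundingBox(
                    label=class_map[cls],
                    x_min=(cx - w / 2.0) * width,
                    y_min=(cy - h / 2.0) * height,
                    x_max=(cx + w / 2.0) * width,
                    y_max=(cy + h / 2.0) * height,
                    confidence=conf,
                )
            )
        frames.append(frame)
    return CameraStream(
        camera_id=camera_id,
        frames=frames,
        frame_rate=frame_rate,
        width=width,
        height=height,
    )


def write_yolo_frames(
    stream: CameraStream,
    directory: PathLike,
    class_map: Optional[Mapping[int, str]] = None,
) -> None:
    """Write one ``frame_<index>.txt`` per frame (inverse of :func:`read_yolo_frames`)."""
    class_map = dict(class_map) if class_map is not None else dict(DEFAULT_YOLO_CLASS_MAP)
    label_to_cls = {name: cls for cls, name in class_map.items()}
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in stream.frames:
        lines = []
        for box in frame.boxes:
            cx = (box.x_min + box.x_max) / 2.0 / stream.width
            cy = (box.y_min + box.y_max) / 2.0 / stream.height
            w = box.width / stream.width
            h = box.height / stream.height
            lines.append(
                f"{label_to_cls[box.label]} {cx:.17g} {cy:.17g} {w:.17g} {h:.17g} {box.confidence:.17g}"
            )
        (directory / f"frame_{frame.frame_index:06d}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else "")
        )


# ---------------------------------------------------------------------------
# Trial manifests and metric tables
# ---------------------------------------------------------------------------

_MANIFEST_FIELDS = ("participant_id", "group", "trial_index", "left_path", "right_path", "frame_rate")


def load_trial_manifest(path: PathLike) -> list[TrialDescriptor]:
    """Load a CSV or JSON manifest into one descriptor per trial.

    Requires columns ``participant_id, group, trial_index, left_path,
    right_path, frame_rate``; optional ``left_truth_path``/``right_truth_path``
    point at ground-truth annotation streams. Duplicate (participant,
    trial) pairs and groups outside {novice, expert} are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return []
        rows = df.to_dict("records")

    descriptors: list[TrialDescriptor] = []
    seen: set[tuple[str, int]] = set()
    for row in rows:
        missing = [f for f in _MANIFEST_FIELDS if f not in row or pd.isna(row[f])]
        if missing:
            raise ValidationError(f"manifest row {row!r} missing fields {missing}")
        desc = TrialDescriptor(
            participant_id=str(row["participant_id"]),
            group=str(row["group"]),
            trial_index=int(row["trial_index"]),
            left_path=str(row["left_path"]),
            right_path=str(row["right_path"]),
            frame_rate=float(row["frame_rate"]),
            left_truth_path=_opt_str(row.get("left_truth_path")),
            right_truth_path=_opt_str(row.get("right_truth_path")),
        )
        key = (desc.participant_id, desc.trial_index)
        if key in seen:
            raise ValidationError(f"duplicate trial {key} in manifest")
        seen.add(key)
        descriptors.append(desc)
    return descriptors


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def write_trial_manifest(descriptors: Sequence[TrialDescriptor], path: PathLike) -> None:
    rows = []
    for d in descriptors:
        row = {f: getattr(d, f) for f in _MANIFEST_FIELDS}
        if d.left_truth_path is not None:
            row["left_truth_path"] = d.left_truth_path
        if d.right_truth_path is not None:
            row["right_truth_path"] = d.right_truth_path
        rows.append(row)
    pd.DataFrame(rows, columns=list(_MANIFEST_FIELDS) if not rows else None).to_csv(
        path, index=False
    )


METRICS_TABLE_COLUMNS: tuple[str, ...] = ("participant_id", "group", "trial_index") + METRIC_NAMES


def write_metrics_table(
    metrics: Iterable[tuple[TrialDescriptor, MetricSet]] | pd.DataFrame,
    path: PathLike,
) -> None:
    """Write one CSV row per trial: three id columns plus the seven metrics.

    Values round-trip at full float precision through
    :func:`read_metrics_table`.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.loc[:, list(METRICS_TABLE_COLUMNS)]
    else:
        rows = []
        for desc, mset in metrics:
            row = {
                "participant_id": desc.participant_id,
                "group": desc.group,
                "trial_index": desc.trial_index,
            }
            row.update(mset.as_dict())
            rows.append(row)
        df = pd.DataFrame(rows, columns=METRICS_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_metrics_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METRICS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metrics table {path} missing columns {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"metrics table {path} has unknown groups {sorted(bad)}")
    return df
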