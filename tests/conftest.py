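import numpy as np
import pytest

from toolmotion import (
    NEEDLE,
    PROBE,
    BoundingBox,
    CameraStream,
    FrameDetections,
    TrialRecording,
)


def box(label=NEEDLE, x0=0.0, y0=0.0, x1=10.0, y1=10.0, conf=1.0) -> BoundingBox:
    return BoundingBox(label, x0, y0, x1, y1, conf)


@pytest.fixture
def make_box():
    return box


def random_stream(rng: np.random.Generator, n_frames: int, camera_id="left") -> CameraStream:
    """Random small stream with intermittent per-tool visibility."""
    frames = []
    for i in range(n_frames):
        boxes = []
        for label in (PROBE, NEEDLE):
            if rng.random() < 0.7:
                x0 = rng.uniform(0, 600)
                y0 = rng.uniform(0, 440)
                boxes.append(
                    BoundingBox(
                        label,
                        x0,
                        y0,
                        x0 + rng.uniform(5, 40),
                        y0 + rng.uniform(5, 40),
                        rng.uniform(0.1, 1.0),
                    )
                )
        frames.append(FrameDetections(frame_index=i, boxes=boxes))
    return CameraStream(camera_id=camera_id, frames=frames, frame_rate=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def stream_from_centers(centers, size=10.0, label=NEEDLE, frame_indices=None, frame_rate=10.0):
    """Stream with one box per listed frame, centered at the given points."""
    if frame_indices is None:
        frame_indices = range(len(centers))
    frames = [
        FrameDetections(
            frame_index=i,
            boxes=[
                BoundingBox(
                    label, cx - size / 2, cy - size / 2, cx + size / 2, cy + size / 2
                )
            ],
        )
        for i, (cx, cy) in zip(frame_indices, centers)
    ]
    return CameraStream(camera_id="left", frames=frames, frame_rate=frame_rate)


def two_camera_trial(left: CameraStream, right: CameraStream, **kwargs) -> TrialRecording:
    right = CameraStream(
        camera_id="right",
        frames=right.frames,
        frame_rate=right.frame_rate,
        width=right.width,
        height=right.height,
    )
    defaults = dict(participant_id="P01", group="novice", trial_index=1)
    defaults.update(kwargs)
    return TrialRecording(streams={"left": left, "right": right}, **defaults)
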