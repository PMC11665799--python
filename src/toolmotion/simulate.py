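"""Synthetic trial generator with the statistical structure the analysis assumes.

No raw procedure videos ship with the package, so studies are emulated as
bounding-box streams: two synchronized 640x480 views at a nominal 10 fps,
trial durations drawn from group-specific log-normals truncated to the
observed 105-672 s range, per-tool visibility following a two-state Markov
chain (the needle enters hidden and surfaces mid-procedure; the probe is
visible most of the time), and tool centers following a target-seeking
AR(1) random walk

    x_{t+1} = x_t + kappa * (target - x_t) + eps_t,   eps_t ~ N(0, sigma^2 I),

clamped so the box stays inside the frame. Detector imperfection is layered
on top: independent per-box misses, Gaussian corner jitter, Beta-distributed
confidences and occasional lower-confidence duplicate boxes; the needle's
noise defaults are worse than the probe's, mirroring its smaller and harder
appearance.

Group defaults encode the effect structure the metrics are meant to detect:
novices take longer (log-normal mean 330 s vs 150 s for experts) and move
more (per-frame step SD 3.0 px vs 2.0 px). Participant-level random effects
correlate trials within a participant, and a mild per-trial learning trend
shrinks duration and step size with trial index. The model is chosen for
its closed-form checks (mean step length sigma*sqrt(pi/2), stationary
visibility p_show/(p_show+p_hide)), not for visual realism.

Everything is driven by explicit integer seeds: identical seeds reproduce
identical studies bit for bit.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import lfilter

from .core import (
    CAMERA_IDS,
    EXPERT,
    GROUPS,
    NEEDLE,
    NOVICE,
    PROBE,
    TOOL_CLASSES,
    BoundingBox,
    CameraStream,
    FrameDetections,
    TrialDescriptor,
    TrialRecording,
    ValidationError,
)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(slots=True)
class GroupMotionParams:
    """Per-group efficiency parameters.

    mean_duration — expected trial length in seconds (log-normal mean);
    duration_dispersion — SD of log duration; step_sd — per-frame, per-axis
    motion noise in pixels; target_attraction — AR(1) pull kappa in [0, 1].
    """

    mean_duration: float
    duration_dispersion: float
    step_sd: float
    target_attraction: float

    def __post_init__(self) -> None:
        if self.mean_duration <= 0:
            raise ValidationError("mean_duration must be > 0")
        if not 0.0 <= self.target_attraction <= 1.0:
            raise ValidationError("target_attraction must be in [0, 1]")
        if self.step_sd < 0 or self.duration_dispersion < 0:
            raise ValidationError("dispersions must be >= 0")


@dataclass(slots=True)
class VisibilityParams:
    """Two-state Markov chain for tool visibility.

    p_hide — per-frame visible->hidden transition; p_show — hidden->visible;
    start_visible — probability the chain starts visible (None = stationary
    probability p_show / (p_show + p_hide)).
    """

    p_hide: float
    p_show: float
    start_visible: Optional[float] = None

    def __post_init__(self) -> None:
        for p in (self.p_hide, self.p_show):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("transition probabilities must be in [0, 1]")

    @property
    def stationary_visible(self) -> float:
        total = self.p_hide + self.p_show
        return self.p_show / total if total > 0 else 1.0


@dataclass(slots=True)
class ToolAppearance:
    """Nominal box size in pixels with per-frame size jitter SD."""

    width: float
    height: float
    size_jitter_sd: float = 0.0


@dataclass(slots=True)
class DetectorNoiseParams:
    """Imperfection of the simulated detector for one tool class."""

    miss_prob: float
    jitter_sd: float
    duplicate_prob: float
    confidence_mean: float
    confidence_concentration: float = 20.0

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.duplicate_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")
        if not 0.0 < self.confidence_mean < 1.0:
            raise ValidationError("confidence_mean must be in (0, 1)")


def _default_groups() -> dict[str, GroupMotionParams]:
    return {
        NOVICE: GroupMotionParams(
            mean_duration=330.0, duration_dispersion=0.35, step_sd=3.0, target_attraction=0.05
        ),
        EXPERT: GroupMotionParams(
            mean_duration=150.0, duration_dispersion=0.35, step_sd=2.0, target_attraction=0.05
        ),
    }


def _default_visibility() -> dict[str, VisibilityParams]:
    # probe on screen ~83% of frames; needle ~50%, entering hidden
    return {
        PROBE: VisibilityParams(p_hide=0.02, p_show=0.10),
        NEEDLE: VisibilityParams(p_hide=0.05, p_show=0.05, start_visible=0.0),
    }


def _default_appearance() -> dict[str, ToolAppearance]:
    return {
        PROBE: ToolAppearance(width=110.0, height=170.0, size_jitter_sd=1.5),
        NEEDLE: ToolAppearance(width=70.0, height=26.0, size_jitter_sd=1.5),
    }


def _default_noise() -> dict[str, DetectorNoiseParams]:
    # needle misses more and localizes worse than the probe
    return {
        PROBE: DetectorNoiseParams(
            miss_prob=0.05, jitter_sd=2.0, duplicate_prob=0.03, confidence_mean=0.88
        ),
        NEEDLE: DetectorNoiseParams(
            miss_prob=0.25, jitter_sd=3.0, duplicate_prob=0.03, confidence_mean=0.70
        ),
    }


@dataclass(slots=True)
class SimulationConfig:
    """Study-level simulation parameters; defaults are the study conditions."""

    frame_rate: float = 10.0
    width: int = 640
    height: int = 480
    duration_bounds: tuple[float, float] = (105.0, 672.0)
    groups: dict[str, GroupMotionParams] = field(default_factory=_default_groups)
    visibility: dict[str, VisibilityParams] = field(default_factory=_default_visibility)
    appearance: dict[str, ToolAppearance] = field(default_factory=_default_appearance)
    noise: dict[str, DetectorNoiseParams] = field(default_factory=_default_noise)
    # right camera moves a little more, as the study's right view ran higher
    camera_step_scale: dict[str, float] = field(
        default_factory=lambda: {"left": 1.0, "right": 1.1}
    )
    participant_duration_sd: float = 0.15
    participant_step_sd: float = 0.10
    learning_rate_duration: float = 0.05
    learning_rate_step: float = 0.05
    n_novices: int = 6
    n_experts: int = 6
    n_trials: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_bounds"] = list(self.duration_bounds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        cfg = cls()
        data = copy.deepcopy(data)
        nested = {
            "groups": GroupMotionParams,
            "visibility": VisibilityParams,
            "appearance": ToolAppearance,
            "noise": DetectorNoiseParams,
        }
        for key, value in data.items():
            if key in nested:
                table = getattr(cfg, key)
                for sub, params in value.items():
                    if isinstance(params, dict):
                        table[sub] = nested[key](**params)
                    else:
                        table[sub] = params
            elif key == "duration_bounds":
                cfg.duration_bounds = (float(value[0]), float(value[1]))
            elif key == "camera_step_scale":
                cfg.camera_step_scale = {str(k): float(v) for k, v in value.items()}
            elif hasattr(cfg, key):
                setattr(cfg, key, type(getattr(cfg, key))(value))
            else:
                raise ValidationError(f"unknown simulation config key {key!r}")
        return cfg


@dataclass(slots=True)
class GroundTruthTrial:
    """A noise-free annotated trial and the noisy detections derived from it."""

    truth: TrialRecording
    detected: TrialRecording

    def __post_init__(self) -> None:
        if self.truth.n_frames != self.detected.n_frames:
            raise ValidationError("detected stream frame count differs from ground truth")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _visibility_chain(
    n: int, params: VisibilityParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample a boolean visibility path of length n by geometric run lengths."""
    out = np.empty(n, dtype=bool)
    if n == 0:
        return out
    start = params.start_visible
    if start is None:
        start = params.stationary_visible
    state = bool(rng.random() < start)
    pos = 0
    while pos < n:
        p_leave = params.p_hide if state else params.p_show
        run = int(rng.geometric(p_leave)) if p_leave > 0 else n - pos
        run = min(run, n - pos)
        out[pos : pos + run] = state
        state = not state
        pos += run
    return out


def _ar1_path(
    n_steps: int,
    x0: float,
    target: float,
    kappa: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions x_1..x_n of the target-seeking AR(1) walk started at x0."""
    eps = rng.normal(0.0, sd, size=n_steps)
    drive = kappa * target + eps
    a = 1.0 - kappa
    path, _ = lfilter([1.0], [1.0, -a], drive, zi=np.array([a * x0]))
    return path


def _tool_track(
    n_frames: int,
    motion: GroupMotionParams,
    appearance: ToolAppearance,
    width: int,
    height: int,
    step_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, 4) ground-truth corner coordinates for one tool in one view."""
    half_w = appearance.width / 2.0
    half_h = appearance.height / 2.0
    # target somewhere in the central half of the frame
    tx = rng.uniform(0.25 * width, 0.75 * width)
    ty = rng.uniform(0.25 * height, 0.75 * height)
    x0 = rng.uniform(0.3 * width, 0.7 * width)
    y0 = rng.uniform(0.3 * height, 0.7 * height)
    sd = motion.step_sd * step_scale
    cx = np.concatenate(
        ([x0], _ar1_path(n_frames - 1, x0, tx, motion.target_attraction, sd, rng))
    ) if n_frames > 1 else np.array([x0])
    cy = np.concatenate(
        ([y0], _ar1_path(n_frames - 1, y0, ty, motion.target_attraction, sd, rng))
    ) if n_frames > 1 else np.array([y0])

    if appearance.size_jitter_sd > 0:
        w = appearance.width + rng.normal(0.0, appearance.size_jitter_sd, n_frames)
        h = appearance.height + rng.normal(0.0, appearance.size_jitter_sd, n_frames)
        w = np.maximum(w, 4.0)
        h = np.maximum(h, 4.0)
    else:
        w = np.full(n_frames, appearance.width)
        h = np.full(n_frames, appearance.height)

    cx = np.clip(cx, half_w, width - half_w)
    cy = np.clip(cy, half_h, height - half_h)
    return np.column_stack((cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))


def _truth_stream(
    camera_id: str,
    n_frames: int,
    motion: GroupMotionParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CameraStream:
    step_scale = config.camera_step_scale.get(camera_id, 1.0)
    tracks, masks = {}, {}
    for tool in TOOL_CLASSES:
        masks[tool] = _visibility_chain(n_frames, config.visibility[tool], rng)
        tracks[tool] = _tool_track(
            n_frames,
            motion,
            config.appearance[tool],
            config.width,
            config.height,
            step_scale,
            rng,
        )
    frames = [FrameDetections(frame_index=i) for i in range(n_frames)]
    for tool in TOOL_CLASSES:
        visible = np.flatnonzero(masks[tool]).tolist()
        coords = tracks[tool]
        x0s, y0s, x1s, y1s = (coords[:, j].tolist() for j in range(4))
        for i in visible:
            frames[i].boxes.append(
                BoundingBox(tool, x0s[i], y0s[i], x1s[i], y1s[i], 1.0)
            )
    return CameraStream(
        camera_id=camera_id,
        frames=frames,
        frame_rate=config.frame_rate,
        width=config.width,
        height=config.height,
    )


def _sample_duration(
    motion: GroupMotionParams,
    bounds: tuple[float, float],
    scale: float,
    rng: np.random.Generator,
) -> float:
    """Log-normal duration with the configured mean, truncated to bounds."""
    mean = motion.mean_duration * scale
    sigma = motion.duration_dispersion
    if sigma == 0.0:
        return float(np.clip(mean, *bounds))
    mu = np.log(mean) - sigma * sigma / 2.0
    for _ in range(1000):
        d = float(rng.lognormal(mu, sigma))
        if bounds[0] <= d <= bounds[1]:
            return d
    return float(np.clip(d, *bounds))


def apply_detector_noise(
    truth: CameraStream, config: SimulationConfig, rng_seed: SeedLike
) -> CameraStream:
    """Derive a noisy detection stream from noise-free annotations.

    Each ground-truth box is independently dropped with its class's
    miss probability; surviving boxes get Gaussian corner jitter and a
    Beta-distributed confidence, and with a small probability a displaced,
    lower-confidence duplicate of the same class is appended.
    """
    rng = _rng(rng_seed)
    entries = [
        (pos, box) for pos, frame in enumerate(truth.frames) for box in frame.boxes
    ]
    n = len(entries)
    boxes_out: list[list[BoundingBox]] = [[] for _ in truth.frames]
    if n:
        labels = np.array([box.label for _, box in entries])
        coords = np.array(
            [(b.x_min, b.y_min, b.x_max, b.y_max) for _, b in entries], dtype=float
        )
        miss_p = np.empty(n)
        jitter_sd = np.empty(n)
        dup_p = np.empty(n)
        conf_a = np.empty(n)
        conf_b = np.empty(n)
        for tool in TOOL_CLASSES:
            p = config.noise[tool]
            sel = labels == tool
            miss_p[sel] = p.miss_prob
            jitter_sd[sel] = p.jitter_sd
            dup_p[sel] = p.duplicate_prob
            conf_a[sel] = p.confidence_mean * p.confidence_concentration
            conf_b[sel] = (1.0 - p.confidence_mean) * p.confidence_concentration

        keep = rng.random(n) >= miss_p
        jitter = rng.normal(0.0, 1.0, (n, 4)) * jitter_sd[:, None]
        conf = rng.beta(conf_a, conf_b)
        duplicate = rng.random(n) < dup_p
        dup_offset = rng.normal(0.0, 1.0, (n, 2)) * (3.0 * jitter_sd[:, None])
        dup_conf = conf * rng.uniform(0.5, 0.9, n)

        fixed = _well_formed(coords + jitter)
        x0s, y0s, x1s, y1s = (fixed[:, j].tolist() for j in range(4))
        conf_list = conf.tolist()
        is_dup = duplicate.tolist()
        for k in np.flatnonzero(keep).tolist():
            pos, src = entries[k]
            x0, y0, x1, y1 = x0s[k], y0s[k], x1s[k], y1s[k]
            boxes_out[pos].append(BoundingBox(src.label, x0, y0, x1, y1, conf_list[k]))
            if is_dup[k]:
                dx, dy = dup_offset[k]
                boxes_out[pos].append(
                    BoundingBox(
                        src.label, x0 + dx, y0 + dy, x1 + dx, y1 + dy, float(dup_conf[k])
                    )
                )
    frames = [
        FrameDetections(frame_index=f.frame_index, boxes=boxes_out[pos])
        for pos, f in enumerate(truth.frames)
    ]
    return CameraStream(
        camera_id=truth.camera_id,
        frames=frames,
        frame_rate=truth.frame_rate,
        width=truth.width,
        height=truth.height,
    )


def _well_formed(coords: np.ndarray) -> np.ndarray:
    """Recenter jittered (n, 4) corner rows whose extent fell below 2 px."""
    out = coords.copy()
    for lo, hi in ((0, 2), (1, 3)):
        narrow = coords[:, hi] - coords[:, lo] < 2.0
        if np.any(narrow):
            center = (coords[narrow, lo] + coords[narrow, hi]) / 2.0
            out[narrow, lo] = center - 1.0
            out[narrow, hi] = center + 1.0
    return out


# ---------------------------------------------------------------------------
# trials and studies
# ---------------------------------------------------------------------------

def simulate_trial(
    config: SimulationConfig,
    group: str,
    rng_seed: SeedLike,
    participant_id: str = "P00",
    trial_index: int = 1,
    duration_scale: float = 1.0,
    step_scale: float = 1.0,
) -> GroundTruthTrial:
    """Simulate one trial: ground-truth streams plus noisy detections.

    ``duration_scale`` and ``step_scale`` multiply the group's mean duration
    and step SD (used for participant random effects and learning trends).
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = _rng(rng_seed)
    motion = config.groups[group]
    motion = replace(
        motion, step_sd=motion.step_sd * step_scale
    )
    duration = _sample_duration(motion, config.duration_bounds, duration_scale, rng)
    n_frames = max(int(round(duration * config.frame_rate)), 1)

    truth_streams: dict[str, CameraStream] = {}
    detected_streams: dict[str, CameraStream] = {}
    for camera_id in CAMERA_IDS:
        truth = _truth_stream(camera_id, n_frames, motion, config, rng)
        truth_streams[camera_id] = truth
        detected_streams[camera_id] = apply_detector_noise(truth, config, rng)

    truth_trial = TrialRecording(
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
        streams=truth_streams,
    )
    detected_trial = TrialRecording(
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
        streams=detected_streams,
        ground_truth=truth_streams,
    )
    return GroundTruthTrial(truth=truth_trial, detected=detected_trial)


def simulate_study(
    config: SimulationConfig, rng_seed: SeedLike
) -> list[GroundTruthTrial]:
    """Simulate the full design: 6 novices + 6 experts, 4 trials each.

    Participant-level log-normal random effects scale duration and step SD
    so trials within a participant correlate; duration and step SD shrink
    by the configured learning rates with each successive trial.
    """
    if isinstance(rng_seed, np.random.Generator):
        raise ValidationError("simulate_study requires an integer or SeedSequence seed")
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    effect_rng = np.random.default_rng(ss.spawn(1)[0])
    participants = [(f"N{i+1:02d}", NOVICE) for i in range(config.n_novices)] + [
        (f"E{i+1:02d}", EXPERT) for i in range(config.n_experts)
    ]
    trial_seeds = iter(ss.spawn(len(participants) * config.n_trials))
    trials: list[GroundTruthTrial] = []
    for pid, group in participants:
        dur_effect = float(np.exp(effect_rng.normal(0.0, config.participant_duration_sd)))
        step_effect = float(np.exp(effect_rng.normal(0.0, config.participant_step_sd)))
        for t in range(1, config.n_trials + 1):
            lf_dur = (1.0 - config.learning_rate_duration) ** (t - 1)
            lf_step = (1.0 - config.learning_rate_step) ** (t - 1)
            trials.append(
                simulate_trial(
                    config,
                    group,
                    next(trial_seeds),
                    participant_id=pid,
                    trial_index=t,
                    duration_scale=dur_effect * lf_dur,
                    step_scale=step_effect * lf_step,
                )
            )
    return trials


def write_study(
    study: Sequence[GroundTruthTrial],
    outdir: Union[str, Path],
    fmt: str = "coco",
    include_truth: bool = True,
) -> Path:
    """Write a simulated study to disk in an interchange format.

    Produces per-trial detection files (and optionally ground truth) plus a
    ``manifest.csv``; returns the manifest path.
    """
    from . import io as tio  # local import to keep module load light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    descriptors = []
    for gt_trial in study:
        trial = gt_trial.detected
        stem = f"{trial.participant_id}_t{trial.trial_index}"
        paths = {}
        for camera_id, stream in trial.streams.items():
            if fmt == "coco":
                path = outdir / f"{stem}_{camera_id}.json"
                tio.write_coco_detections(stream, path)
            elif fmt == "yolo":
                path = outdir / f"{stem}_{camera_id}"
                tio.write_yolo_frames(stream, path)
            else:
                raise ValidationError(f"unknown format {fmt!r}")
            paths[camera_id] = path
        truth_paths: dict[str, Optional[Path]] = {"left": None, "right": None}
        if include_truth and fmt == "coco":
            for camera_id, stream in gt_trial.truth.streams.items():
                tp = outdir / f"{stem}_{camera_id}_truth.json"
                tio.write_coco_detections(stream, tp)
                truth_paths[camera_id] = tp
        descriptors.append(
            TrialDescriptor(
                participant_id=trial.participant_id,
                group=trial.group,
                trial_index=trial.trial_index,
                left_path=str(paths["left"]),
                right_path=str(paths["right"]),
                frame_rate=trial.frame_rate,
                left_truth_path=(
                    str(truth_paths["left"]) if truth_paths["left"] else None
                ),
                right_truth_path=(
                    str(truth_paths["right"]) if truth_paths["right"] else None
                ),
            )
        )
    manifest = outdir / "manifest.csv"
    tio.write_trial_manifest(descriptors, manifest)
    return manifest
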