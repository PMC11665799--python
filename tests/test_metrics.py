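"""Best-box filtering, usage times and the two path-length metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toolmotion import (
    NEEDLE,
    PROBE,
    BoundingBox,
    CameraStream,
    FrameDetections,
    TrialRecording,
    ValidationError,
    center_path_length,
    corner_path_length,
    select_best_boxes,
    total_procedure_time,
    trial_metrics,
    usage_time,
    visibility_series,
)
from toolmotion.metrics import VisibilitySeries

from conftest import box, random_stream, stream_from_centers, two_camera_trial


# --- independent brute-force oracles -----------------------------------------

def brute_center_path(entries):
    total = 0.0
    for (_, a), (_, b) in zip(entries, entries[1:]):
        ca = ((a.x_min + a.x_max) / 2, (a.y_min + a.y_max) / 2)
        cb = ((b.x_min + b.x_max) / 2, (b.y_min + b.y_max) / 2)
        total += math.dist(ca, cb)
    return total


def brute_corner_path(entries):
    total = 0.0
    for (_, a), (_, b) in zip(entries, entries[1:]):
        for ca, cb in zip(a.corners, b.corners):
            total += math.dist(ca, cb)
    return total


class TestSelectBestBoxes:
    def test_highest_confidence_per_class_kept(self):
        frame = FrameDetections(
            0, [box(NEEDLE, conf=0.9), box(NEEDLE, 1, 1, 11, 11, conf=0.7)]
        )
        out = select_best_boxes(frame)
        assert [b.confidence for b in out.boxes] == [0.9]

    def test_different_classes_unaffected(self):
        frame = FrameDetections(0, [box(PROBE, conf=0.5), box(NEEDLE, conf=0.6)])
        assert len(select_best_boxes(frame).boxes) == 2

    def test_tie_keeps_earliest_listed(self):
        first = box(PROBE, 0, 0, 10, 10, conf=0.8)
        second = box(PROBE, 5, 5, 15, 15, conf=0.8)
        out = select_best_boxes(FrameDetections(0, [first, second]))
        assert out.boxes == [first]

    def test_empty_frame_maps_to_empty(self):
        assert select_best_boxes(FrameDetections(3)).boxes == []


class TestVisibilityAndTimes:
    def test_series_contains_exactly_detected_frames(self):
        frames = [
            FrameDetections(i, [box(NEEDLE)] if i in {1, 2, 5} else [])
            for i in range(6)
        ]
        stream = CameraStream("left", frames, frame_rate=10)
        series = visibility_series(stream, NEEDLE)
        assert [i for i, _ in series.entries] == [1, 2, 5]

    def test_never_detected_gives_empty_series(self):
        stream = CameraStream("left", [FrameDetections(0)], frame_rate=10)
        assert len(visibility_series(stream, NEEDLE)) == 0

    def test_unknown_tool_rejected(self):
        stream = CameraStream("left", [], frame_rate=10)
        with pytest.raises(ValidationError, match="unknown tool"):
            visibility_series(stream, "scalpel")

    @pytest.mark.parametrize(
        "n_frames,expected", [(1050, 105.0), (6720, 672.0), (0, 0.0)]
    )
    def test_total_time_is_frames_over_rate(self, n_frames, expected):
        frames = [FrameDetections(i) for i in range(n_frames)]
        trial = two_camera_trial(
            CameraStream("left", frames, 10.0),
            CameraStream("left", list(frames), 10.0),
        )
        assert total_procedure_time(trial) == expected

    def test_unsynchronized_streams_rejected(self):
        left = CameraStream("left", [FrameDetections(0)], 10.0)
        right = CameraStream("right", [FrameDetections(0), FrameDetections(1)], 10.0)
        with pytest.raises(ValidationError, match="synchronized"):
            TrialRecording("P01", "novice", 1, {"left": left, "right": right})

    @pytest.mark.parametrize("n_visible,expected", [(50, 5.0), (0, 0.0), (37, 3.7)])
    def test_usage_time(self, n_visible, expected):
        frames = [
            FrameDetections(i, [box(NEEDLE)] if i < n_visible else [])
            for i in range(60)
        ]
        stream = CameraStream("left", frames, frame_rate=10)
        assert usage_time(stream, NEEDLE) == pytest.approx(expected)


class TestPathLengths:
    def test_center_path_three_four_five(self):
        series = visibility_series(stream_from_centers([(0, 0), (3, 4)]), NEEDLE)
        assert center_path_length(series) == pytest.approx(5.0)

    def test_single_visible_frame_is_zero(self):
        series = visibility_series(stream_from_centers([(7, 9)]), NEEDLE)
        assert center_path_length(series) == 0.0
        assert corner_path_length(series) == 0.0

    def test_gap_bridged_not_skipped(self):
        stream = stream_from_centers([(0, 0), (6, 8)], frame_indices=[1, 3])
        series = visibility_series(stream, NEEDLE)
        assert center_path_length(series) == pytest.approx(10.0)

    def test_corner_path_translation_is_four_centers(self):
        series = visibility_series(stream_from_centers([(0, 0), (3, 4)]), NEEDLE)
        assert corner_path_length(series) == pytest.approx(20.0)

    def test_corner_path_static_box_is_zero(self):
        series = visibility_series(stream_from_centers([(5, 5), (5, 5)]), NEEDLE)
        assert corner_path_length(series) == 0.0

    def test_corner_path_box_growth(self):
        frames = [
            FrameDetections(0, [box(NEEDLE, 0, 0, 2, 2)]),
            FrameDetections(1, [box(NEEDLE, 0, 0, 4, 4)]),
        ]
        series = visibility_series(CameraStream("left", frames, 10), NEEDLE)
        assert corner_path_length(series) == pytest.approx(4 + 2 * math.sqrt(2))

    def test_centered_symmetric_growth_moves_corners_not_center(self):
        frames = [
            FrameDetections(0, [box(NEEDLE, -1, -1, 1, 1)]),
            FrameDetections(1, [box(NEEDLE, -2, -2, 2, 2)]),
        ]
        series = visibility_series(CameraStream("left", frames, 10), NEEDLE)
        assert center_path_length(series) == 0.0
        assert corner_path_length(series) > 0.0

    @given(
        steps=st.lists(
            st.tuples(
                st.floats(-20, 20).map(lambda v: round(v, 3)),
                st.floats(-20, 20).map(lambda v: round(v, 3)),
            ),
            min_size=2,
            max_size=10,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_translation_only_motion_relates_paths_by_four(self, steps):
        centers = np.cumsum(np.array(steps), axis=0) + 100.0
        series = visibility_series(stream_from_centers(centers.tolist()), NEEDLE)
        assert corner_path_length(series) == pytest.approx(
            4 * center_path_length(series), rel=1e-9
        )

    def test_global_translation_invariance_and_scaling(self, rng):
        centers = rng.uniform(50, 400, size=(12, 2))
        base = visibility_series(stream_from_centers(centers.tolist()), NEEDLE)
        shifted = visibility_series(
            stream_from_centers((centers + [13.5, -7.25]).tolist()), NEEDLE
        )
        scaled = visibility_series(
            stream_from_centers((centers * 3.0).tolist(), size=30.0), NEEDLE
        )
        for path in (center_path_length, corner_path_length):
            assert path(shifted) == pytest.approx(path(base), rel=1e-12)
            assert path(scaled) == pytest.approx(3.0 * path(base), rel=1e-12)

    def test_removing_invisible_frames_changes_nothing(self, rng):
        stream = random_stream(rng, 40)
        series = visibility_series(stream, NEEDLE)
        compact = CameraStream(
            "left",
            [f for f in stream.frames if any(b.label == NEEDLE for b in f.boxes)],
            10.0,
        )
        compact_series = visibility_series(compact, NEEDLE)
        assert center_path_length(series) == pytest.approx(
            center_path_length(compact_series), rel=1e-12
        )
        assert corner_path_length(series) == pytest.approx(
            corner_path_length(compact_series), rel=1e-12
        )

    def test_matches_brute_force_on_random_streams(self, rng):
        for _ in range(100):
            stream = random_stream(rng, int(rng.integers(2, 50)))
            for tool in (PROBE, NEEDLE):
                series = visibility_series(stream, tool)
                assert center_path_length(series) == pytest.approx(
                    brute_center_path(series.entries), rel=1e-9, abs=1e-12
                )
                assert corner_path_length(series) == pytest.approx(
                    brute_corner_path(series.entries), rel=1e-9, abs=1e-12
                )


class TestTrialMetrics:
    def test_two_camera_maximum_rule(self):
        left = stream_from_centers([(0, 0), (30, 40)])  # 50 px
        right = stream_from_centers([(0, 0), (60, 80)])  # 100 px
        trial = two_camera_trial(left, right)
        metrics = trial_metrics(trial)
        assert metrics.center_path_needle == pytest.approx(100.0)
        assert metrics.corner_path_needle == pytest.approx(400.0)

    def test_identical_streams_match_single_stream(self, rng):
        stream = random_stream(rng, 25)
        trial = two_camera_trial(stream, stream)
        single = TrialRecording("P01", "novice", 1, {"left": stream})
        assert trial_metrics(trial) == trial_metrics(single)

    def test_one_camera_values_pass_through(self, rng):
        stream = random_stream(rng, 25)
        single = TrialRecording("P01", "novice", 1, {"left": stream})
        metrics = trial_metrics(single)
        series = visibility_series(stream, NEEDLE)
        assert metrics.center_path_needle == pytest.approx(center_path_length(series))
        assert metrics.usage_time_needle == pytest.approx(len(series) / 10.0)

    def test_usage_time_bounded_by_total_time(self, rng):
        for seed in range(5):
            stream = random_stream(np.random.default_rng(seed), 30)
            trial = two_camera_trial(stream, random_stream(np.random.default_rng(seed + 99), 30))
            m = trial_metrics(trial)
            assert 0 <= m.usage_time_probe <= m.total_procedure_time
            assert 0 <= m.usage_time_needle <= m.total_procedure_time
            assert min(m.as_dict().values()) >= 0

    def test_multi_box_frames_filtered_before_metrics(self):
        # a far-away low-confidence needle box must not inflate the path
        frames = [
            FrameDetections(0, [box(NEEDLE, 0, 0, 10, 10, conf=0.9)]),
            FrameDetections(
                1,
                [
                    box(NEEDLE, 0, 0, 10, 10, conf=0.8),
                    box(NEEDLE, 500, 400, 510, 410, conf=0.2),
                ],
            ),
        ]
        stream = CameraStream("left", frames, 10.0)
        single = TrialRecording("P01", "novice", 1, {"left": stream})
        assert trial_metrics(single).center_path_needle == pytest.approx(0.0)
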