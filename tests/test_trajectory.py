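import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormstate.trajectory import (
    MotionConfig,
    StageLog,
    classify_motion,
    detect_reversals_freely_moving,
    fill_gaps,
    reconstruct_path,
)


def stage(n, xy=None, fps=2.0):
    xy = np.zeros((n, 2)) if xy is None else np.asarray(xy, float)
    return StageLog(xy=xy, times=np.arange(n) / fps)


class TestReconstruction:
    def test_static_stage_roi_drift(self):
        """ROI moving +10 px/frame at 1 um/px on a static stage gives a
        world speed of 10 um/frame."""
        n = 20
        roi = np.column_stack([10.0 * np.arange(n), np.zeros(n)])
        world = reconstruct_path(stage(n), roi, pixel_size=1.0, smooth_window=None)
        steps = np.diff(world[:, 0])
        np.testing.assert_allclose(steps, 10.0)

    def test_stage_compensation_cancels(self):
        """A stage moving exactly against the ROI drift yields a constant
        world path."""
        n = 20
        roi = np.column_stack([2.0 * np.arange(n), np.zeros(n)])
        stage_xy = np.column_stack([-2.0 * np.arange(n), np.zeros(n)])
        world = reconstruct_path(stage(n, stage_xy), roi, smooth_window=None)
        assert np.ptp(world[:, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same frames"):
            reconstruct_path(stage(5), np.zeros((4, 2)))

    def test_orientation_transform(self):
        n = 4
        roi = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        world = reconstruct_path(stage(n), roi, orientation="rot90", smooth_window=None)
        np.testing.assert_allclose(world[:, 1], roi[:, 0])
        np.testing.assert_allclose(world[:, 0], 0.0, atol=1e-12)

    def test_smoothing_preserves_length(self):
        n = 31
        roi = np.random.default_rng(0).normal(0, 1, (n, 2))
        world = reconstruct_path(stage(n), roi, smooth_window=5)
        assert len(world) == n
        assert np.isfinite(world).all()

    def test_generator_world_path_recovered(self, clean_stack):
        from wormstate.neuron_tracker import track_heuristic

        roi = track_heuristic(clean_stack, seed_xy=tuple(clean_stack.truth_path[0]))
        world = reconstruct_path(
            StageLog(clean_stack.stage_log, clean_stack.times),
            roi,
            pixel_size=clean_stack.pixel_size,
            frame_shape=clean_stack.frame_shape,
            smooth_window=None,
        )
        rms = np.sqrt(np.mean(np.sum((world - clean_stack.truth_world) ** 2, axis=1)))
        assert rms <= 1.0  # one pixel-equivalent


def path_with_gap(n, gap_start, gap_len, step=5.0):
    path = np.column_stack([step * np.arange(n), 0.5 * np.arange(n)])
    path[gap_start : gap_start + gap_len] = np.nan
    return path


class TestGapFilling:
    def test_29_frame_gap_filled(self):
        path, excluded = fill_gaps(path_with_gap(120, 40, 29))
        assert not excluded[40:69].any()
        assert np.isfinite(path).all()

    def test_30_frame_gap_excluded(self):
        path, excluded = fill_gaps(path_with_gap(120, 40, 30))
        assert excluded[40:70].all()
        assert not excluded[:40].any() and not excluded[70:].any()

    def test_boundary_gap_never_extrapolated(self):
        path, excluded = fill_gaps(path_with_gap(60, 0, 5))
        assert excluded[:5].all()
        path, excluded = fill_gaps(path_with_gap(60, 55, 5))
        assert excluded[55:].all()

    def test_collinear_fill_is_exact(self):
        """A gap inside uniform linear motion is filled on the line."""
        filled, _ = fill_gaps(path_with_gap(60, 20, 10))
        expect_x = 5.0 * np.arange(20, 30)
        np.testing.assert_allclose(filled[20:30, 0], expect_x, atol=1e-8)
        np.testing.assert_allclose(filled[20:30, 1], 0.5 * np.arange(20, 30), atol=1e-8)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        start=st.integers(min_value=5, max_value=80),
        gap=st.integers(min_value=1, max_value=45),
    )
    def test_gap_rule_exact_at_any_placement(self, start, gap):
        """29/30 boundary behavior holds wherever the gap falls."""
        n = 140
        if start + gap > n - 5:
            gap = n - 5 - start
        filled, excluded = fill_gaps(path_with_gap(n, start, gap))
        inside = excluded[start : start + gap]
        if gap < 30:
            assert not inside.any()
        else:
            assert inside.all()


class TestMotionClassification:
    def run(self, path, fps=2.0, cfg=None):
        return classify_motion(np.asarray(path, float), fps, cfg or MotionConfig())

    def straight(self, seconds, speed=50.0, fps=2.0):
        n = int(seconds * fps)
        return np.column_stack([speed / fps * np.arange(n), np.zeros(n)])

    def test_long_straight_run_is_forward(self):
        motion = self.run(self.straight(100.0))
        assert (motion["label"] == "forward").all()

    def test_short_straight_run_needs_label(self):
        motion = self.run(self.straight(60.0))
        assert (motion["label"] == "needs_label").all()

    def test_exactly_90s_needs_label(self):
        motion = self.run(self.straight(90.0))
        assert (motion["label"] == "needs_label").all()

    def test_slow_drift_is_stationary(self):
        n = 100
        path = np.column_stack([5.0 / 2.0 * np.arange(n), np.zeros(n)])  # 5 um/s
        motion = self.run(path)
        assert (motion["label"] == "stationary").all()

    def test_consistent_angle_boundary(self):
        """Per-frame heading changes of exactly 7.5 degrees keep a run
        consistent; 8 degrees breaks it."""
        fps = 2.0
        for ddeg, n_runs in ((7.5, 1), (8.0, None)):
            heading = np.radians(np.cumsum(np.full(240, ddeg)))
            steps = 30.0 * np.column_stack([np.cos(heading), np.sin(heading)])
            path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            motion = self.run(path, fps=fps)
            runs = motion.loc[motion["run_id"] >= 0, "run_id"].nunique()
            if n_runs is not None:
                assert runs == n_runs
            else:
                assert runs > 100  # every frame breaks the run


class TestReversalDetection:
    def test_labeled_toy_sequence(self):
        fps = 2.0
        fwd = np.column_stack([25.0 * np.arange(40), np.zeros(40)])
        back = fwd[-1] - np.column_stack([25.0 * np.arange(1, 11), np.zeros(10)])
        fwd2 = back[-1] + np.column_stack([25.0 * np.arange(1, 41), np.zeros(40)])
        path = np.vstack([fwd, back, fwd2])
        motion = classify_motion(path, fps)
        run_ids = motion.loc[motion["label"] == "needs_label", "run_id"].unique()
        # label middle run backward, flanks forward
        manual = {}
        for rid in run_ids:
            frames = motion.loc[motion["run_id"] == rid, "frame"]
            manual[int(rid)] = "backward" if frames.iloc[0] >= 40 and frames.iloc[-1] < 52 else "forward"
        events = detect_reversals_freely_moving(motion, manual)
        assert len(events) == 1
        assert abs(int(events.loc[0, "onset_frame"]) - 40) <= 1

    def test_no_backward_runs_no_events(self):
        motion = classify_motion(
            np.column_stack([50.0 * np.arange(30), np.zeros(30)]), 2.0
        )
        events = detect_reversals_freely_moving(motion, {})
        assert events.empty

    def test_pipeline_recovers_scheduled_reversals(self):
        """Reconstruction + classification recovers >= 95% of scheduled
        reversal events from stage-log + ROI tracks at default noise."""
        from wormstate.synthetic_data import stage_follow

        fps = 2.0
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            segments = []
            t = 0.0
            while t < 600.0:
                fwd = rng.uniform(60.0, 150.0)
                segments.append(("forward", fwd))
                t += fwd
                if t >= 600.0:
                    break
                back = rng.uniform(3.0, 8.0)
                segments.append(("backward", back))
                t += back
            pos = [np.zeros(2)]
            heading = rng.uniform(0, 2 * np.pi)
            truth = []
            for state, dur in segments:
                for _ in range(int(dur * fps)):
                    if state == "forward":
                        heading += rng.normal(0, np.radians(2.0))
                        direction = heading
                    else:
                        direction = heading + np.pi
                    truth.append(state)
                    pos.append(pos[-1] + 50.0 / fps * np.array(
                        [np.cos(direction), np.sin(direction)]))
            world = np.asarray(pos[:-1])
            truth = np.asarray(truth, object)
            n = len(world)
            stage_xy = stage_follow(world, deadband_um=15.0)
            roi = (world - stage_xy) + np.array([63.5, 63.5])
            roi += np.random.default_rng(seed + 99).normal(0, 0.3, (n, 2))
            rec = reconstruct_path(
                StageLog(stage_xy, np.arange(n) / fps), roi, frame_shape=(128, 128)
            )
            filled, excl = fill_gaps(rec)
            motion = classify_motion(filled, fps, excluded=excl)
            manual = {}
            for rid, grp in motion[motion["label"] == "needs_label"].groupby("run_id"):
                states, counts = np.unique(
                    truth[grp["frame"].to_numpy()], return_counts=True
                )
                manual[int(rid)] = str(states[np.argmax(counts)])
            events = detect_reversals_freely_moving(motion, manual)
            onsets = [
                i for i in range(1, n)
                if truth[i] == "backward" and truth[i - 1] != "backward"
            ]
            total += len(onsets)
            for onset in onsets:
                if np.any(np.abs(events["onset_frame"].to_numpy() - onset) <= 2):
                    hits += 1
        assert total >= 20
        assert hits / total >= 0.95

    def test_unlabeled_runs_warn_and_excluded(self):
        path = np.column_stack([25.0 * np.arange(60), np.zeros(60)])  # 30 s run
        motion = classify_motion(path, 2.0)
        with pytest.warns(UserWarning, match="unlabeled"):
            events = detect_reversals_freely_moving(motion, {})
        assert events.empty
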