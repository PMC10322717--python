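"""Pattern-space dynamics: speed, slow points, heading angles, durations."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from camopath.core import FeatureTrajectory
from camopath.dynamics import (
    SpeedProfile,
    background_correlation_progress,
    change_duration,
    classify_heading_model,
    detect_epochs,
    detect_transitions,
    find_slow_points,
    heading_angles,
    pattern_speed,
    rayleigh_test,
    step_statistics,
)
from conftest import make_trajectory


def profile(values, rate=25.0):
    v = np.asarray(values, dtype=float)
    return SpeedProfile((np.arange(v.size) + 0.5) / rate, v, 2, 0.0, rate)


class TestPatternSpeed:
    def test_static_trajectory_zero_speed(self):
        traj = FeatureTrajectory(np.ones((100, 3)))
        sp = pattern_speed(traj)
        assert np.allclose(sp.values[~np.isnan(sp.values)], 0.0)

    def test_uniform_linear_motion(self):
        v = 3.0  # units per second
        t = np.arange(200) / 25.0
        traj = FeatureTrajectory(np.outer(t * v, [0.6, 0.8]))
        sp = pattern_speed(traj)
        mid = sp.values[30:-30]
        assert np.allclose(mid, v, rtol=1e-6)

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(80, 5)).cumsum(axis=0)
        Q = ortho_group.rvs(5, random_state=1)
        s1 = pattern_speed(FeatureTrajectory(coords), n_pcs=5)
        s2 = pattern_speed(FeatureTrajectory(coords @ Q), n_pcs=5)
        ok = ~np.isnan(s1.values)
        assert np.allclose(s1.values[ok], s2.values[ok])

    def test_gap_propagation(self):
        traj = FeatureTrajectory(np.arange(100, dtype=float)[:, None])
        valid = np.ones(100, bool)
        valid[40:45] = False
        sp = pattern_speed(traj, valid_mask=valid, smooth=0.0)
        assert np.isnan(sp.values[39:45]).all()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pattern_speed(FeatureTrajectory(np.zeros((2, 2))))


class TestSlowPoints:
    def test_monotone_profile_has_none(self):
        slow = find_slow_points(profile(np.linspace(0, 10, 100)))
        assert slow.n_points == 0

    def test_planted_minima_recovered(self):
        # uniform-step (memory) trajectory: clean, comparable speed bumps
        traj, truth = make_trajectory("memory", seed=8, noise=0.2, n_waypoints=6,
                                      T=1100, dwell=60)
        sp = pattern_speed(traj)
        slow = find_slow_points(sp)
        planted = truth.slow_point_frames
        assert slow.n_points == planted.size
        assert np.all(np.abs(slow.indices - planted) <= 2)

    def test_symmetric_v_dwell_symmetric(self):
        v = np.abs(np.arange(-30, 31, dtype=float)) + 1.0
        slow = find_slow_points(profile(v))
        assert slow.n_points == 1
        a, b = slow.dwell_intervals[0]
        m = slow.indices[0]
        assert abs((m - a) - (b - m)) <= 1

    def test_count_non_increasing_in_smoothing(self):
        rng = np.random.default_rng(3)
        raw = np.abs(rng.normal(0, 1, 400).cumsum() + 10)
        traj = FeatureTrajectory(np.cumsum(np.c_[raw, raw * 0.5], axis=0) / 25.0)
        counts = []
        for smooth in (0.4, 1.0, 2.0, 4.0):
            sp = pattern_speed(traj, smooth=smooth)
            counts.append(find_slow_points(sp).n_points)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestStepStatistics:
    def test_one_dimensional_binning(self):
        # slow points at x = 100, 50, 10; goal 0; bin 55 -> counts [2, 1]
        coords = np.zeros((6, 2))
        coords[:, 0] = [120, 100, 50, 10, 5, 0]
        traj = FeatureTrajectory(coords)
        slow = find_slow_points(profile(np.array([5, 1, 5, 1, 5, 1, 5.0])))
        # construct annotation manually at indices of the three slow points
        from camopath.core import SlowPointAnnotation

        ann = SlowPointAnnotation(np.array([1, 2, 3]), [(1, 1), (2, 2), (3, 3)],
                                  np.zeros(6, bool), 0.0)
        out = step_statistics(traj, ann, goal=np.zeros(2), bin_width=55.0)
        assert out["step_counts"].tolist() == [2, 1]

    def test_slow_point_at_goal_first_bin(self):
        from camopath.core import SlowPointAnnotation

        traj = FeatureTrajectory(np.zeros((4, 2)))
        ann = SlowPointAnnotation(np.array([2]), [(2, 2)], np.zeros(4, bool), 0.0)
        out = step_statistics(traj, ann, goal=np.zeros(2))
        assert out["distances"][0] == 0 and out["step_counts"][0] == 1


class TestHeadingAngles:
    def test_straight_path_zero_angles(self):
        coords = np.linspace([0, 0], [10, 10], 11)
        traj = FeatureTrajectory(coords)
        from camopath.core import SlowPointAnnotation

        ann = SlowPointAnnotation(np.array([3, 6, 9]), [(3, 3), (6, 6), (9, 9)],
                                  np.zeros(11, bool), 0.0)
        ha = heading_angles(traj, ann, start=coords[0], goal=coords[-1])
        assert np.allclose(ha.alpha, 0) and np.allclose(ha.beta, 0)

    def test_hand_geometry(self):
        # path (0,0)->(1,0)->(1,1), start (0,0), goal (1,1)
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        traj = FeatureTrajectory(coords)
        from camopath.core import SlowPointAnnotation

        ann = SlowPointAnnotation(np.array([1, 2]), [(1, 1), (2, 2)],
                                  np.zeros(3, bool), 0.0)
        ha = heading_angles(traj, ann, start=coords[0], goal=np.array([1.0, 1.0]))
        # step 2: exit (0,1); alpha vs goal-from-(1,0) = (0,1) -> 0
        assert np.isclose(ha.alpha[1], 0.0)
        # beta vs start->goal (1,1): 45 degrees
        assert np.isclose(abs(ha.beta[1]), np.pi / 4)

    def test_model_contrast_on_simulations(self):
        correct = 0
        n_runs = 20
        for s in range(n_runs):
            for model in ("update", "memory"):
                traj, _ = make_trajectory(model, seed=s)
                sp = pattern_speed(traj)
                ha = heading_angles(traj, find_slow_points(sp))
                correct += classify_heading_model(ha) == model
        assert correct / (2 * n_runs) >= 0.95


class TestRayleigh:
    def test_identical_angles_maximal_concentration(self):
        rbar, z, p = rayleigh_test(np.full(10, 0.7))
        assert np.isclose(rbar, 1.0) and np.isclose(z, 10.0)
        assert p < 1e-3

    def test_antipodal_cancellation(self):
        rbar, _, p = rayleigh_test(np.tile([0.0, np.pi], 10))
        assert rbar < 1e-12 and p > 0.9

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, 50))[2] < 0.05
            for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.02

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.zeros(4))


class TestChangeDuration:
    def test_triangular_pulse_crossing_arithmetic(self):
        # 0 -> 1 -> 0 over 10 s, baseline 0: crossings at 0.5 and 9.5 s
        rate = 25.0
        t = np.arange(int(10 * rate) + 1) / rate
        v = np.where(t <= 5, t / 5, (10 - t) / 5)
        sp = SpeedProfile(t, v, 2, 0.0, rate)
        out = change_duration(sp, baseline=0.0)
        assert abs(out["duration"] - 9.0) < 0.05

    def test_baseline_shift_invariance(self):
        rate = 25.0
        t = np.arange(int(10 * rate) + 1) / rate
        v = np.where(t <= 5, t / 5, (10 - t) / 5)
        d1 = change_duration(SpeedProfile(t, v, 2, 0.0, rate), baseline=0.0)
        d2 = change_duration(SpeedProfile(t, v + 2.0, 2, 0.0, rate), baseline=2.0)
        assert np.isclose(d1["duration"], d2["duration"])

    def test_two_pulses_span_vs_per_pulse(self):
        rate = 25.0
        t = np.arange(int(20 * rate)) / rate
        v = np.exp(-0.5 * ((t - 4) / 0.8) ** 2) + np.exp(-0.5 * ((t - 14) / 0.8) ** 2)
        sp = SpeedProfile(t, v, 2, 0.0, rate)
        span = change_duration(sp, baseline=0.0)
        pulses = change_duration(sp, baseline=0.0, mode="per-pulse")
        assert len(pulses["events"]) == 2
        assert span["duration"] > max(e[2] for e in pulses["events"])

    def test_flat_profile_is_error(self):
        sp = profile(np.full(100, 2.0))
        with pytest.raises(ValueError, match="no event"):
            change_duration(sp, baseline=2.0)


class TestTransitionsAndEpochs:
    def test_single_step_one_chunk(self):
        coords = np.zeros((26 * 60, 2))
        coords[26 * 30:] = [10.0, 0.0]
        chunks = detect_transitions(FeatureTrajectory(coords), subsample=5)
        assert len(chunks) == 1
        lo, hi = chunks[0]
        assert lo <= 26 * 30 - 1 <= hi + 1

    def test_merge_rule_20s(self):
        rate = 25.0
        T = int(90 * rate)
        coords = np.zeros((T, 2))
        coords[int(30 * rate):] += [10.0, 0]
        coords[int(40 * rate):] += [0, 10.0]   # 10 s later: merged
        merged = detect_transitions(FeatureTrajectory(coords), subsample=5)
        assert len(merged) == 1
        coords2 = np.zeros((T, 2))
        coords2[int(20 * rate):] += [10.0, 0]
        coords2[int(50 * rate):] += [0, 10.0]  # 30 s later: separate
        two = detect_transitions(FeatureTrajectory(coords2), subsample=5)
        assert len(two) == 2

    def test_epochs_planted_dip_splits_period(self):
        rate = 25.0
        T = int(60 * rate)
        corr = np.full(T - 1, 0.95)
        corr[int(30 * rate): int(35 * rate)] = 0.5  # 5 s dip
        centroids = np.zeros((T, 2))
        out = detect_epochs(centroids, corr, rate=rate)
        assert len(out["periods"]) == 2
        assert out["motion_epochs"] == []

    def test_stationary_centroid_no_motion(self):
        rate = 25.0
        T = int(30 * rate)
        out = detect_epochs(np.zeros((T, 2)), np.full(T - 1, 0.99), rate=rate)
        assert out["motion_epochs"] == []


class TestBackgroundCorrelation:
    def test_convergence_to_background(self, rng):
        bg = rng.normal(size=50)
        start = rng.normal(size=50)
        steps = np.linspace(0, 1, 12)[:, None]
        coords = start[None, :] * (1 - steps) + bg[None, :] * steps
        traj = FeatureTrajectory(coords)
        from camopath.core import SlowPointAnnotation

        idx = np.arange(1, 12)
        ann = SlowPointAnnotation(idx, [(i, i) for i in idx], np.zeros(12, bool), 0.0)
        delta = background_correlation_progress(traj, ann, bg)
        assert np.all(np.diff(delta) >= -1e-9)
        r_onset = np.corrcoef(start, bg)[0, 1]
        assert np.isclose(delta[-1], 1 - r_onset, atol=1e-9)

    def test_constant_background_rejected(self):
        traj = FeatureTrajectory(np.random.default_rng(0).normal(size=(5, 10)))
        from camopath.core import SlowPointAnnotation

        ann = SlowPointAnnotation(np.array([2]), [(2, 2)], np.zeros(5, bool), 0.0)
        with pytest.raises(ValueError):
            background_correlation_progress(traj, ann, np.ones(10))
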