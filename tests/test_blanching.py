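"""Blanching trials: selection, recruitment ranks, memory, curvature."""

import numpy as np
import pytest

from camopath import synth
from camopath.blanching import (
    aggregate_ranks,
    bytrial_vs_alltrial_variance,
    component_rank_test,
    event_patterns,
    fast_phase,
    mantel_test,
    pattern_memory_clustering,
    rank_density,
    recruitment_times,
    select_blanch_trials,
    select_similar_trials,
    trajectory_curvature,
)
from camopath.core import AreaMatrix, ComponentPartition, FeatureTrajectory, TrajectoryTruth
from camopath.dynamics import SpeedProfile


class TestTrialSelection:
    @pytest.mark.parametrize(
        "depth,in_kept,in_components",
        [(0.3, True, True), (0.6, True, False), (0.95, False, False)],
    )
    def test_two_tier_filter(self, small_scene, depth, in_kept, in_components):
        am, _ = synth.gen_blanch_trial(small_scene, 300, [0, 1, 2], depth, seed=0)
        out = select_blanch_trials([am])
        assert (0 in out["kept"]) is in_kept
        assert (0 in out["kept_components"]) is in_components

    def test_short_trial_rejected(self):
        am = AreaMatrix(np.ones((50, 3)))
        out = select_blanch_trials([am])
        assert out["rejected"][0][1].startswith("trial shorter")


class TestFastPhase:
    def test_rectangular_pulse_support(self):
        rate = 25.0
        v = np.zeros(1000)
        v[200:400] = 1.0   # outward pulse
        v[600:900] = 0.5   # return pulse
        sp = SpeedProfile(np.arange(1000) / rate, v, 2, 0.0, rate)
        out_mask, ret_mask = fast_phase(sp, split_frame=500)
        half = int(4.0 * rate) // 2
        on = np.flatnonzero(out_mask)
        assert abs(on[0] - 200) <= half and abs(on[-1] - 399) <= half
        assert not out_mask[500:].any() and not ret_mask[:500].any()

    def test_zero_speed_is_error(self):
        sp = SpeedProfile(np.arange(100) / 25.0, np.zeros(100), 2, 0.0, 25.0)
        with pytest.raises(ValueError, match="zero peak"):
            fast_phase(sp, split_frame=50)


class TestRecruitment:
    def test_clean_step_onset_location(self):
        rate = 25.0
        T, N = 300, 5
        vals = np.full((T, N), 2.0)
        step_frames = [150, 170, 190, 210, 230]
        for i, f in enumerate(step_frames):
            vals[f:, i] = 10.0
        vals[100:110] = 1.0  # blanch minimum at ~105
        am = AreaMatrix(vals, rate=rate)
        onsets, ranks = recruitment_times(am)
        assert np.all(np.abs(onsets - step_frames) <= rate / 2 + 1)
        assert ranks.tolist() == [1, 2, 3, 4, 5]

    def test_tied_onsets_average_rank(self):
        vals = np.full((200, 3), 1.0)
        vals[:100] = 0.2
        vals[100:, 2] = 0.2
        vals[150:, 2] = 1.0  # third recruits later; first two tie
        am = AreaMatrix(vals)
        _, ranks = recruitment_times(am)
        assert ranks.tolist() == [1.5, 1.5, 3.0]

    def test_flat_trace_excluded(self):
        vals = np.full((200, 2), 1.0)
        vals[:, 0] = np.linspace(1.0, 0.2, 200)  # monotone decrease only
        am = AreaMatrix(vals + 1e-9)
        onsets, _ = recruitment_times(am)
        assert np.isnan(onsets).all()


class TestRankDensity:
    def test_degenerate_point_masses(self):
        r = aggregate_ranks(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        rd = rank_density(r, n_bins=10)
        assert np.allclose(rd.sigma_bins, 0.0)
        assert rd.bin_density.sum() == 3

    def test_half_probability_closed_form(self):
        # n chromatophores each with p = 0.5 in one bin -> sigma = sqrt(n/4)
        from camopath.blanching import RecruitmentRanks

        n = 16
        mu = np.full(n, 0.05)   # centered on the first-bin edge of 10 bins
        sigma = np.full(n, 1e-6)
        mu[:] = 0.10            # exactly at the boundary between bins 0 and 1
        r = RecruitmentRanks(np.tile(mu, (2, 1)), mu, sigma)
        rd = rank_density(r, n_bins=10)
        assert np.isclose(rd.sigma_bins[0], np.sqrt(n * 0.25), rtol=1e-3)

    def test_formula_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n, n_bins = 40, 20
        mu = rng.uniform(0, 1, n)
        sigma = rng.uniform(0.02, 0.2, n)
        from camopath.blanching import RecruitmentRanks

        rd = rank_density(RecruitmentRanks(np.tile(mu, (2, 1)), mu, sigma), n_bins)
        draws = rng.normal(mu, sigma, size=(10000, n))
        # draws outside [0,1] fall in no bin, matching the Bernoulli model
        counts = np.stack([np.histogram(d, bins=rd.bin_edges)[0] for d in draws])
        mc_sd = counts.std(axis=0)
        big = rd.sigma_bins > 0.5
        assert np.all(np.abs(mc_sd[big] - rd.sigma_bins[big]) / rd.sigma_bins[big] < 0.10)


class TestComponentRankTest:
    def test_hand_computed_kruskal_wallis(self):
        # groups {1,2}, {3,4}, {5,6}: H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2)
        mu = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        part = ComponentPartition(np.array([0, 0, 1, 1, 2, 2]))
        out = component_rank_test(mu, part, n_perm=50, seed=0)
        assert np.isclose(out["H"], 12 / 42 * 2 * (4 + 0 + 4))

    def test_disjoint_ranges_significant(self):
        rng = np.random.default_rng(1)
        mu = np.r_[rng.uniform(0, 0.2, 20), rng.uniform(0.8, 1.0, 20)]
        part = ComponentPartition(np.repeat([0, 1], 20))
        out = component_rank_test(mu, part, n_perm=500, seed=0)
        assert out["p"] < 0.01
        assert out["pairwise_p_bh"][0] < 0.01

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            component_rank_test(np.arange(5.0), ComponentPartition(np.zeros(5, int)))


class TestPatternMemory:
    def test_identical_structures_high_cophenetic(self, rng):
        B = rng.normal(size=(8, 30))
        out = pattern_memory_clustering(B, B + rng.normal(0, 1e-6, B.shape),
                                        n_perm=499, seed=0)
        assert out["cophenetic_r"] > 0.99
        assert out["mantel_p"] < 0.05

    def test_planted_families_conserved(self, rng):
        # two trial families preserved from blanch to end
        fam = np.repeat([0, 1], 5)
        proto = rng.normal(size=(2, 40))
        B = proto[fam] + 0.1 * rng.normal(size=(10, 40))
        E = 2.5 * proto[fam] + 0.1 * rng.normal(size=(10, 40))
        out = pattern_memory_clustering(B, E, n_perm=499, seed=1)
        from scipy.cluster.hierarchy import fcluster

        for Z in (out["linkage_blanch"], out["linkage_end"]):
            lab = fcluster(Z, t=2, criterion="maxclust")
            assert len(set(lab[fam == 0])) == 1 and len(set(lab[fam == 1])) == 1
        assert out["mantel_p"] < 0.05

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pattern_memory_clustering(np.ones((5, 10)), np.ones((5, 10)))

    def test_event_patterns_average_window(self):
        am = AreaMatrix(np.arange(40, dtype=float)[:, None] @ np.ones((1, 2)))
        pat = event_patterns(am, frame=20, window=10)
        assert np.allclose(pat, np.mean(np.arange(15, 25)))


class TestCurvature:
    def test_straight_line_any_dimension(self, rng):
        d = rng.normal(size=5)
        coords = np.linspace(0, 1, 200)[:, None] * d * 100
        cp = trajectory_curvature(FeatureTrajectory(coords))
        assert cp.mean_curvature < 1e-6

    def test_circle_closed_form(self):
        R, ds = 40.0, 1.0
        th = np.linspace(0, 1.6 * np.pi, 3000)
        coords = np.column_stack([R * np.cos(th), R * np.sin(th)])
        cp = trajectory_curvature(FeatureTrajectory(coords), step=ds)
        expected = 2 * np.sin(ds / (2 * R))
        assert abs(cp.mean_curvature - expected) / expected < 0.01

    def test_rigid_motion_and_reparameterization_invariance(self, rng):
        th = np.linspace(0, 2.2, 400) ** 1.5  # non-uniform traversal speed
        coords = np.column_stack([30 * np.cos(th), 30 * np.sin(th)])
        base = trajectory_curvature(FeatureTrajectory(coords)).mean_curvature
        ang = 0.7
        Rm = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = coords @ Rm.T + np.array([100.0, -50.0])
        rot = trajectory_curvature(FeatureTrajectory(moved)).mean_curvature
        assert abs(rot - base) / base < 1e-6
        # uniform reparameterization: every other sample, same geometry
        sub = trajectory_curvature(FeatureTrajectory(coords[::2])).mean_curvature
        assert abs(sub - base) / base < 0.01

    def test_ballistic_straighter_than_meandering(self):
        lower = 0
        for s in range(5):
            tb = TrajectoryTruth("ballistic", start=np.zeros(2),
                                 goal=np.array([80.0, 50.0]), dwell_frames=20)
            trajb = synth.gen_transition_trajectory(tb, 500, seed=s)
            cb = trajectory_curvature(trajb, fast_mask=tb.outward_mask)
            tm = TrajectoryTruth("update", start=np.zeros(2),
                                 goal=np.array([80.0, 50.0]), noise_sd=0.25,
                                 n_waypoints=8, dwell_frames=20)
            trajm = synth.gen_transition_trajectory(tm, 800, seed=s)
            cm = trajectory_curvature(trajm)
            lower += cb.mean_curvature < cm.mean_curvature
        assert lower == 5

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            trajectory_curvature(FeatureTrajectory(np.zeros((10, 2))))


class TestMantel:
    def test_permutation_null_uniformity(self, rng):
        # under independence the p-value is approximately uniform
        ps = []
        for s in range(100):
            g = np.random.default_rng(s)
            d1 = np.abs(g.normal(size=(8, 8)))
            d2 = np.abs(g.normal(size=(8, 8)))
            d1, d2 = (d1 + d1.T) / 2, (d2 + d2.T) / 2
            np.fill_diagonal(d1, 0)
            np.fill_diagonal(d2, 0)
            ps.append(mantel_test(d1, d2, n_perm=99, seed=s)[1])
        assert abs(np.mean(np.asarray(ps) < 0.05) - 0.05) < 0.06


class TestByTrialVsAllTrial:
    def _trials(self, shared: bool, n_trials=3, N=90, seed=0):
        trials = []
        rng = np.random.default_rng(seed)
        base_labels = np.arange(N) % 3
        for t in range(n_trials):
            labels = base_labels if shared else rng.permutation(base_labels)
            tt = np.arange(250) / 25.0
            load = np.stack([10 + 3 * np.sin(2 * np.pi * (0.15 + 0.07 * k) * tt + k + t)
                             for k in range(3)])
            vals = load[labels].T + rng.normal(0, 0.3, (250, N))
            trials.append(AreaMatrix(np.clip(vals, 0, None)))
        return trials

    def test_shared_structure_ratio_near_one(self):
        out = bytrial_vs_alltrial_variance(self._trials(shared=True), resolution=1.0)
        assert np.all(out["ratio"] < 1.15)

    def test_trial_specific_structure_ratio_above_one(self):
        out = bytrial_vs_alltrial_variance(self._trials(shared=False), resolution=1.0)
        assert out["ratio"].mean() > 1.0
        assert np.all(out["shuffled"] <= out["by_trial"] + 1e-12)

    def test_similar_trial_selection(self, rng):
        trajs = [FeatureTrajectory(rng.normal(0, 1, (20, 2))) for _ in range(4)]
        trajs += [FeatureTrajectory(rng.normal(500, 1, (20, 2)))]
        sel = select_similar_trials(trajs, cut_distance=100.0)
        assert sorted(sel) == [0, 1, 2, 3]
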