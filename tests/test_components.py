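"""Component decomposition, partition matching and stability metrics."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from camopath.components import (
    active_components,
    checkerboard_regression,
    leiden_components,
    match_partitions,
    reconstruction_variance,
    shuffled_partition,
    spatial_separation,
    stability_vs_distance,
    transition_distance,
)
from camopath.core import AreaMatrix, ComponentPartition, FeatureTrajectory
from conftest import planted_component_matrix


def brute_force_mean_iou(l1, l2):
    """Oracle: best mean IoU over all one-to-one component pairings."""
    u1, u2 = np.unique(l1), np.unique(l2)
    sets1 = {a: set(np.flatnonzero(l1 == a)) for a in u1}
    sets2 = {b: set(np.flatnonzero(l2 == b)) for b in u2}
    k = min(len(u1), len(u2))
    best = -1.0
    for rows in itertools.permutations(u1, k):
        for cols in itertools.permutations(u2, k):
            ious = [
                len(sets1[a] & sets2[b]) / len(sets1[a] | sets2[b])
                for a, b in zip(rows, cols)
            ]
            best = max(best, float(np.mean(ious)))
    return best


class TestLeiden:
    def test_planted_components_recovered(self):
        am, labels = planted_component_matrix(150, 5, seed=2)
        part = leiden_components(am, resolution=1.0, seed=2)
        assert adjusted_rand_score(labels, part.labels) > 0.95

    def test_single_loading_one_component(self):
        rng = np.random.default_rng(0)
        base = 10 + 3 * np.sin(np.arange(200) / 10.0)
        vals = np.clip(base[:, None] + rng.normal(0, 0.3, (200, 40)), 0, None)
        part = leiden_components(AreaMatrix(vals), resolution=0.5, seed=0)
        assert part.k == 1

    def test_resolution_monotonicity(self):
        for seed in range(5):
            am, _ = planted_component_matrix(100, 3, seed=seed)
            k_hi = leiden_components(am, resolution=2.0, seed=seed).k
            k_lo = leiden_components(am, resolution=0.5, seed=seed).k
            assert k_hi >= k_lo

    def test_too_few_chromatophores_rejected(self):
        with pytest.raises(ValueError):
            leiden_components(AreaMatrix(np.random.default_rng(0).uniform(size=(50, 5))))


class TestActiveComponents:
    def test_planted_one_active_of_three(self):
        rng = np.random.default_rng(1)
        T, per = 200, 10
        ramp = np.linspace(0, 5, T)
        vals = np.column_stack(
            [np.tile(10 + rng.normal(0, 0.2, (T, 1)), (1, per)),          # flat noisy
             np.tile((10 + ramp)[:, None], (1, per)) + rng.normal(0, 0.2, (T, per)),
             np.full((T, per), 4.0)]                                      # constant
        )
        part = ComponentPartition(np.repeat([0, 1, 2], per))
        am = AreaMatrix(np.clip(vals, 0, None))
        assert active_components(part, am).tolist() == [1]

    def test_empty_phase_rejected(self):
        am = AreaMatrix(np.ones((50, 4)))
        part = ComponentPartition(np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="empty phase"):
            active_components(part, am, phase_mask=np.zeros(50, bool))


class TestReconstruction:
    def test_singleton_partition_exact(self, planted_areas):
        part = ComponentPartition(np.arange(planted_areas.n_chrom))
        ev = reconstruction_variance(part, planted_areas)
        assert abs(ev - 1.0) < 1e-10

    def test_global_component_on_anticorrelated_pair(self):
        # two perfectly anticorrelated chromatophores share one component:
        # the component mean is constant, explaining none of the variance
        t = np.sin(np.arange(100) / 5.0)
        vals = np.column_stack([5 + t, 5 - t])
        part = ComponentPartition(np.zeros(2, dtype=int))
        ev = reconstruction_variance(part, AreaMatrix(vals))
        assert abs(ev) < 1e-10

    def test_same_partition_beats_shuffled(self):
        for seed in range(5):
            am, _ = planted_component_matrix(80, 4, seed=seed)
            part = leiden_components(am, resolution=1.0, seed=seed)
            ev = reconstruction_variance(part, am)
            ev_sh = reconstruction_variance(part, am, mode="shuffled", seed=seed)
            assert ev > ev_sh


class TestMatchPartitions:
    def test_identical_partitions(self):
        p = ComponentPartition(np.array([0, 0, 1, 1, 2]))
        m = match_partitions(p, p)
        assert m.mean_iou == 1.0 and m.ari == 1.0
        assert m.wallace == (1.0, 1.0)

    def test_hand_worked_example(self):
        p1 = ComponentPartition(np.array([0, 0, 0, 1, 1]))
        p2 = ComponentPartition(np.array([0, 0, 1, 1, 1]))
        m = match_partitions(p1, p2)
        assert np.isclose(m.mean_iou, 2.0 / 3.0)
        assert m.pairs == [(0, 0), (1, 1)]

    def test_optimal_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(6, 14)
            l1 = rng.integers(0, rng.integers(2, 5), n)
            l2 = rng.integers(0, rng.integers(2, 5), n)
            l1[: l1.max() + 1] = np.arange(l1.max() + 1)
            l2[: l2.max() + 1] = np.arange(l2.max() + 1)
            m = match_partitions(ComponentPartition(l1), ComponentPartition(l2),
                                 method="optimal")
            assert np.isclose(m.mean_iou, brute_force_mean_iou(l1, l2))

    def test_random_partitions_ari_near_zero(self):
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(100):
            l1 = rng.integers(0, 4, 100)
            l2 = rng.integers(0, 4, 100)
            aris.append(match_partitions(ComponentPartition(l1),
                                         ComponentPartition(l2)).ari)
        assert abs(np.mean(aris)) < 0.05

    def test_disjoint_universes_rejected(self):
        p1 = ComponentPartition(np.array([0, 1]), chrom_ids=[0, 1])
        p2 = ComponentPartition(np.array([0, 1]), chrom_ids=[5, 6])
        with pytest.raises(ValueError):
            match_partitions(p1, p2)


class TestDistances:
    def test_single_point_hand_arithmetic(self):
        d = transition_distance(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), 1.0)
        assert np.isclose(d, 5.0)

    def test_symmetry_and_identity(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(7, 3))
        assert np.isclose(transition_distance(a, b, 2.0), transition_distance(b, a, 2.0))
        assert transition_distance(np.zeros((1, 2)), np.zeros((1, 2))) == 0.0

    def test_stability_decreases_with_distance(self):
        # progressive membership reshuffling along a distance axis
        rng = np.random.default_rng(4)
        N, K = 60, 3
        base_labels = np.arange(N) % K
        parts, trajs = [], []
        for step in range(6):
            labels = base_labels.copy()
            n_flip = 8 * step
            idx = rng.choice(N, n_flip, replace=False)
            labels[idx] = rng.integers(0, K, n_flip)
            parts.append(ComponentPartition(labels))
            trajs.append(FeatureTrajectory(
                np.full((5, 2), 10.0 * step) + rng.normal(0, 0.1, (5, 2))))
        out = stability_vs_distance(parts, trajs, dataset_sd=1.0, seed=0)
        r = np.corrcoef(out["distance"], out["mean_iou"])[0, 1]
        assert r < -0.3
        assert out["shuffled_iou"].mean() < out["mean_iou"].mean()


class TestSpatial:
    def test_identical_clouds(self):
        pos = np.random.default_rng(0).uniform(0, 100, (40, 2))
        part = ComponentPartition(np.r_[np.zeros(20, int), np.ones(20, int)],
                                  chrom_ids=np.arange(40))
        pos2 = np.vstack([pos[:20], pos[:20]])
        out = spatial_separation(part, pos2)
        pair = out[(0, 1)]
        assert pair["wasserstein"] < 1e-9 and pair["overlap"] > 1 - 1e-9

    def test_one_dimensional_closed_form(self):
        part = ComponentPartition(np.array([0, 1]))
        pos = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = spatial_separation(part, pos)
        assert np.isclose(out[(0, 1)]["wasserstein"], 10.0)

    def test_interleaved_overlaps_more_than_blocks(self):
        x = np.arange(40, dtype=float)
        inter = np.column_stack([x, np.zeros(40)])
        lab_inter = (np.arange(40) % 2)
        blocks = inter.copy()
        lab_blocks = (np.arange(40) >= 20).astype(int)
        p1 = ComponentPartition(lab_inter)
        p2 = ComponentPartition(lab_blocks)
        o1 = spatial_separation(p1, inter, bin_px=4)[(0, 1)]["overlap"]
        o2 = spatial_separation(p2, blocks, bin_px=4)[(0, 1)]["overlap"]
        assert o1 > o2


class TestCheckerboardRegression:
    def test_exact_log_linear(self):
        sizes = np.array([0.2, 0.4, 0.8, 1.6])
        means = 2.0 * np.log(sizes)
        out = checkerboard_regression(means, sizes)
        assert np.isclose(out["slope"], 2.0) and np.isclose(out["r2"], 1.0)

    def test_constant_response_not_significant(self):
        sizes = np.geomspace(0.2, 2.4, 8)
        rng = np.random.default_rng(0)
        out = checkerboard_regression(5.0 + rng.normal(0, 0.01, 8), sizes)
        assert abs(out["slope"]) < 0.1 and out["p"] > 0.05

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            checkerboard_regression(np.ones(4), np.array([5.0, 8.0, 10.0, 20.0]))
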