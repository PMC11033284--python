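import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from ricestore.grading import (GradeModel, MIndexSample, build_m_index,
                               grade_clusters, kmeans, select_k, silhouette)
from ricestore.synthetic import generate_tiered_m_samples


def exhaustive_best_inertia(points: np.ndarray, K: int) -> float:
    """Global optimum by enumerating every assignment of points to K parts."""
    best = np.inf
    n = len(points)
    for assignment in itertools.product(range(K), repeat=n):
        if len(set(assignment)) != K:
            continue
        labels = np.array(assignment)
        inertia = 0.0
        for j in range(K):
            members = points[labels == j]
            inertia += float(((members - members.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


FOUR_POINTS = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0]])


class TestBuildMIndex:
    def test_identity_pair(self):
        m = build_m_index(1.2, 1.1, "imidacloprid")
        assert m.as_array().tolist() == [1.2, 1.1]

    def test_zero_pair_allowed(self):
        assert build_m_index(0.0, 0.0).as_array().tolist() == [0.0, 0.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            build_m_index(-0.1, 0.2)


class TestKMeans:
    def test_two_well_separated_pairs(self):
        res = kmeans(FOUR_POINTS, K=2, seed=0)
        centers = sorted(res.centers[:, 0])
        assert centers == pytest.approx([0.05, 5.05])
        assert res.inertia == pytest.approx(0.01)
        assert res.inertia == pytest.approx(
            exhaustive_best_inertia(FOUR_POINTS, 2))

    def test_k1_is_the_mean(self, rng):
        pts = rng.normal(size=(10, 2))
        res = kmeans(pts, K=1, seed=0)
        assert np.allclose(res.centers[0], pts.mean(axis=0))

    def test_k_equals_n_zero_inertia(self, rng):
        pts = rng.normal(size=(5, 2)) * 10
        res = kmeans(pts, K=5, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_invalid_k(self, rng):
        pts = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            kmeans(pts, K=5)
        with pytest.raises(ValueError):
            kmeans(pts, K=0)

    @pytest.mark.parametrize("n,K", [(6, 2), (7, 2), (8, 2), (6, 3), (8, 3)])
    def test_global_optimality_small_instances(self, n, K):
        # with 10 restarts Lloyd should land on the enumerated optimum
        rng = np.random.default_rng(n * 10 + K)
        for trial in range(4):
            pts = rng.uniform(0, 3, size=(n, 2))
            res = kmeans(pts, K=K, seed=trial, restarts=10)
            assert res.inertia == pytest.approx(
                exhaustive_best_inertia(pts, K), rel=1e-9, abs=1e-12)

    def test_fixed_point_assignment(self, rng):
        pts = rng.normal(size=(30, 2))
        res = kmeans(pts, K=3, seed=1)
        d2 = ((pts[:, None, :] - res.centers[None]) ** 2).sum(axis=2)
        assert np.array_equal(np.argmin(d2, axis=1), res.labels)
        for j in range(3):
            assert np.allclose(res.centers[j],
                               pts[res.labels == j].mean(axis=0))


class TestSilhouette:
    def test_hand_worked_four_points(self):
        labels = np.array([0, 0, 1, 1])
        s = silhouette(FOUR_POINTS, labels)
        # per-sample: (5.05-0.1)/5.05, (4.95-0.1)/4.95 and symmetric
        expected = 0.5 * ((5.05 - 0.1) / 5.05 + (4.95 - 0.1) / 4.95)
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(0.9800, abs=1e-4)

    def test_coincident_clusters_score_one(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 0], [3, 0]])
        assert silhouette(pts, np.array([0, 0, 1, 1])) == 1.0

    def test_all_points_coincident_zero_by_convention(self):
        pts = np.zeros((4, 2))
        assert silhouette(pts, np.array([0, 0, 1, 1])) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            silhouette(FOUR_POINTS, np.zeros(4, dtype=int))

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(40, 2))
            labels = rng.integers(0, 3, size=40)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(pts, labels) == pytest.approx(
                silhouette_score(pts, labels), abs=1e-12)

    def test_singleton_cluster_contributes_zero(self):
        pts = np.array([[0.0, 0], [0.1, 0], [5, 0]])
        labels = np.array([0, 0, 1])
        # by hand: singleton contributes 0; others ~ (b-a)/max
        a0, b0 = 0.1, 5.0
        a1, b1 = 0.1, 4.9
        expected = ((b0 - a0) / b0 + (b1 - a1) / b1 + 0.0) / 3
        assert silhouette(pts, labels) == pytest.approx(expected, abs=1e-12)


class TestSelectK:
    def test_recovers_three_tiers(self):
        pts, _ = generate_tiered_m_samples([0.5, 2.0, 3.5], 0.25, 40, seed=0)
        best, scores = select_k(pts, range(3, 8), seed=0)
        assert best == 3
        assert set(scores) == {3, 4, 5, 6, 7}

    def test_recovers_seven_tiers(self):
        centers = np.arange(1.0, 8.0)  # separation/sd = 1/0.08 >> 6
        pts, _ = generate_tiered_m_samples(centers, 0.08, 25, seed=1)
        best, _ = select_k(pts, range(3, 8), seed=1)
        assert best == 7

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(5, 2)), range(3, 8))

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(30, 2)), [])


class TestGradeClusters:
    def test_midpoint_breakpoints_worked_example(self):
        pts = np.array([[0.5, 0.4], [0.6, 0.5], [1.0, 0.9], [1.1, 1.0],
                        [2.0, 1.8]])
        res = kmeans(pts, K=3, seed=0)
        gm = grade_clusters(res, pts)
        assert gm.breakpoints == pytest.approx([0.8, 1.55])
        assert gm.grade_names == ("High", "Medium", "Low")
        assert gm.intervals() == [("High", "(0, 0.8)"),
                                  ("Medium", "[0.8, 1.55]"),
                                  ("Low", "(1.55, +inf)")]

    def test_two_cluster_grades(self):
        pts = np.array([[0.1, 0.1], [0.2, 0.1], [3.0, 2.9], [3.1, 3.0]])
        gm = grade_clusters(kmeans(pts, K=2, seed=0), pts)
        assert gm.grade_names == ("High", "Low")
        assert len(gm.breakpoints) == 1

    def test_grade_monotone_in_center(self):
        pts, _ = generate_tiered_m_samples([0.5, 2.0, 4.0], 0.2, 30, seed=3)
        gm = grade_clusters(kmeans(pts, K=3, seed=0), pts)
        assert np.all(np.diff(gm.centers[:, 0]) > 0)

    def test_interval_grade_agrees_with_membership(self):
        pts, _ = generate_tiered_m_samples([0.5, 2.0, 4.0], 0.2, 30, seed=4)
        res = kmeans(pts, K=3, seed=0)
        gm = grade_clusters(res, pts)
        for p, lab in zip(pts, res.labels):
            by_interval = gm.grade_of_value(p[0])
            by_cluster = gm.grade_names[gm.cluster_to_grade[lab]]
            if p[0] not in gm.breakpoints:
                assert by_interval == by_cluster

    def test_breakpoint_value_falls_in_closed_interval(self):
        gm = GradeModel(K=3, grade_names=("High", "Medium", "Low"),
                        breakpoints=np.array([1.0, 2.0]),
                        centers=np.zeros((3, 2)), counts=np.zeros(3, int),
                        cluster_to_grade=np.arange(3))
        assert gm.grade_of_value(1.0) == "Medium"
        assert gm.grade_of_value(2.0) == "Medium"
        assert gm.grade_of_value(0.5) == "High"
        assert gm.grade_of_value(2.5) == "Low"

    def test_overlapping_clusters_rejected(self):
        # hand-built interleaved clustering whose midpoint cuts come out
        # non-increasing
        pts = np.array([[0.0, 0], [5.0, 0], [1.0, 0], [6.0, 0], [3.0, 0]])
        from ricestore.grading import ClusterResult
        bad = ClusterResult(K=3, labels=np.array([0, 0, 1, 1, 2]),
                            centers=np.array([[2.5, 0.0], [3.5, 0.0],
                                              [3.0, 0.0]]),
                            inertia=1.0)
        with pytest.raises(ValueError, match="overlap"):
            grade_clusters(bad, pts)

    def test_planted_tier_recovery_rate(self):
        # 3 tiers, separation/sd = 6: select_k should find 3 nearly always
        hits = 0
        for seed in range(20):
            pts, _ = generate_tiered_m_samples([1.0, 2.5, 4.0], 0.25, 40,
                                               seed=seed)
            best, _ = select_k(pts, range(3, 8), seed=seed)
            hits += best == 3
        assert hits >= 18
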