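"""Benchmark metrics against exhaustive/brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spagnet import (EdgeRanking, GroundTruthNetwork, SpotCoordinates,
                     auroc_auprc, clustering_ari, knn_neighbors, morans_i,
                     stability, tf_universe)
from spagnet.spatial_graph import SpatialGraph


def sweep_auroc(labels, scores):
    """Trapezoidal ROC area from an exhaustive threshold sweep."""
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    p, n = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores >= t
        pts.append(((pred & ~labels).sum() / n, (pred & labels).sum() / p))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    return sum((x2 - x1) * (y1 + y2) / 2
               for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]))


def sweep_auprc(labels, scores):
    """Average precision from an exhaustive threshold sweep."""
    thresholds = np.unique(scores)[::-1]
    ap, prev_recall = 0.0, 0.0
    p = labels.sum()
    for t in thresholds:
        pred = scores >= t
        tp = (pred & labels).sum()
        recall = tp / p
        precision = tp / pred.sum()
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAurocAuprc:
    def universe(self):
        return tf_universe(["G0", "G1", "G2", "G3"], ["G0", "G1"])

    def test_perfect_ranking_auroc_one(self):
        truth = GroundTruthNetwork({("G0", "G2"), ("G1", "G3")})
        uni = self.universe()
        entries = [(a, b, 1.0 if (a, b) in truth.edges else 0.1)
                   for a, b in uni]
        auroc, auprc = auroc_auprc(EdgeRanking(entries), truth, uni)
        assert auroc == pytest.approx(1.0)
        assert auprc == pytest.approx(1.0)

    def test_reversed_ranking_auroc_zero(self):
        truth = GroundTruthNetwork({("G0", "G2"), ("G1", "G3")})
        uni = self.universe()
        entries = [(a, b, 0.1 if (a, b) in truth.edges else 1.0)
                   for a, b in uni]
        auroc, _ = auroc_auprc(EdgeRanking(entries), truth, uni)
        assert auroc == pytest.approx(0.0)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        uni = self.universe()
        entries = [(a, b, float(rng.choice([0.1, 0.4, 0.4, 0.9, rng.random()])))
                   for a, b in uni]
        edges = {uni[i] for i in rng.choice(len(uni), size=2, replace=False)}
        truth = GroundTruthNetwork(edges)
        auroc, auprc = auroc_auprc(EdgeRanking(entries), truth, uni)
        scores = EdgeRanking(entries).scores_over(uni)
        labels = np.array([p in truth.edges for p in uni])
        assert auroc == pytest.approx(sweep_auroc(labels, scores), abs=1e-10)
        assert auprc == pytest.approx(sweep_auprc(labels, scores), abs=1e-10)

    def test_unranked_edges_score_zero(self):
        truth = GroundTruthNetwork({("G0", "G2")})
        uni = self.universe()
        ranking = EdgeRanking([("G0", "G2", 0.9)])  # others implicit at 0
        auroc, _ = auroc_auprc(ranking, truth, uni)
        assert auroc == pytest.approx(1.0)

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError):
            GroundTruthNetwork(set()).n_edges or auroc_auprc(
                EdgeRanking([]), GroundTruthNetwork(set()), [])

    def test_random_ranking_auroc_near_half(self):
        rng = np.random.default_rng(0)
        uni = tf_universe([f"G{i}" for i in range(8)], ["G0", "G1", "G2"])
        truth = GroundTruthNetwork({("G0", "G5"), ("G1", "G6"), ("G2", "G7")})
        aurocs = []
        for _ in range(200):
            entries = [(a, b, float(rng.random())) for a, b in uni]
            aurocs.append(auroc_auprc(EdgeRanking(entries), truth, uni)[0])
        # mean of U/(n1 n2) for random scores is 0.5 with s.e. ~ sd/sqrt(200)
        se = np.std(aurocs) / np.sqrt(len(aurocs))
        assert abs(np.mean(aurocs) - 0.5) < 3 * se + 1e-3


class TestStability:
    def ranking(self, scores):
        pairs = [("G0", f"G{i+1}") for i in range(len(scores))]
        return EdgeRanking([(a, b, s) for (a, b), s in zip(pairs, scores)])

    def test_identical_runs(self):
        r = self.ranking([0.9, 0.5, 0.3, 0.2, 0.1])
        sp, jac = stability([r, self.ranking([0.9, 0.5, 0.3, 0.2, 0.1])], k=2)
        assert sp == [pytest.approx(1.0)]
        assert jac == [pytest.approx(1.0)]

    def test_disjoint_topk_zero_jaccard(self):
        a = self.ranking([0.9, 0.8, 0.1, 0.1, 0.1])
        b = self.ranking([0.1, 0.1, 0.1, 0.9, 0.8])
        _, jac = stability([a, b], k=2)
        assert jac == [pytest.approx(0.0)]

    def test_five_edge_toy_matches_rank_formula(self):
        s1 = [5.0, 4.0, 3.0, 2.0, 1.0]
        s2 = [3.0, 5.0, 1.0, 4.0, 2.0]
        sp, _ = stability([self.ranking(s1), self.ranking(s2)], k=3)
        # Spearman from the exact rank-difference formula (no ties)
        from scipy.stats import rankdata
        d = rankdata(s1) - rankdata(s2)
        expected = 1 - 6 * (d ** 2).sum() / (5 * 24)
        assert sp[0] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_universes_error(self):
        a = self.ranking([1.0, 0.5])
        b = EdgeRanking([("G9", "G1", 1.0), ("G9", "G2", 0.5)])
        with pytest.raises(ValueError, match="universe"):
            stability([a, b], k=1)


class TestMoransI:
    def two_spot_graph(self):
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        return SpatialGraph(B=b, neighbor_sets=[np.array([1]), np.array([0])],
                            k=1)

    def test_constant_field_errors(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(2), self.two_spot_graph())

    def test_two_spot_antithetic_is_minus_one(self):
        assert morans_i(np.array([1.0, -1.0]),
                        self.two_spot_graph()) == pytest.approx(-1.0)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(8)
        coords = SpotCoordinates(rng.uniform(0, 10, size=(30, 2)))
        nb = knn_neighbors(coords, k=4)
        w = np.zeros((30, 30))
        for j, nbs in enumerate(nb):
            w[nbs, j] = 1.0
        w = np.maximum(w, w.T)
        x = rng.normal(size=30)
        got = morans_i(x, w)
        dev = x - x.mean()
        num = sum(w[i, j] * dev[i] * dev[j]
                  for i in range(30) for j in range(30))
        expected = 30 / w.sum() * num / (dev ** 2).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        coords = SpotCoordinates(rng.uniform(0, 5, size=(20, 2)))
        nb = knn_neighbors(coords, k=3)
        graph = SpatialGraph(
            B=np.eye(20), neighbor_sets=nb, k=3)
        w = np.zeros((20, 20))
        for j, nbs in enumerate(nb):
            w[nbs, j] = 1.0
        x = rng.normal(size=20)
        assert morans_i(x, w) == pytest.approx(
            morans_i(5.0 * x - 3.0, w), abs=1e-12)


class TestARI:
    def test_identical_partitions(self):
        assert clustering_ari([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster_contingency_formula(self):
        a = list(range(6))
        b = [0] * 6
        # expected-adjusted value from the pair-counting formula is 0
        assert clustering_ari(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        relabeled = (truth + 1) % 3
        assert clustering_ari(pred, truth) == pytest.approx(
            clustering_ari(pred, relabeled), abs=1e-12)

    def test_single_spot_errors(self):
        with pytest.raises(ValueError):
            clustering_ari([0], [0])
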