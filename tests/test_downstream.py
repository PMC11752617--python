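"""Regulon extraction/pruning, AUCell activity, Leiden clustering and the
specificity filter."""

import numpy as np
import pandas as pd
import pytest

from spagnet import (ActivityMatrix, AttentionNetwork, ClusterLabels,
                     ExpressionMatrix, PassThroughMotifBackend, Regulon,
                     aucell_activity, cluster_spots, extract_regulons,
                     prune_regulons, specific_regulons)


def net_from(s, genes):
    return AttentionNetwork(S=np.asarray(s, dtype=float), gene_ids=genes)


class TestExtractRegulons:
    def test_single_dominant_entry(self):
        s = np.zeros((3, 3))
        s[0, 2] = 1.0
        regs = extract_regulons(net_from(s, ["T0", "G1", "G2"]), ["T0"],
                                top_k=1, min_targets=1)
        assert len(regs) == 1
        assert regs[0].targets == ["G2"]

    def test_zero_row_tie_break_deterministic(self):
        s = np.zeros((3, 3))
        regs = extract_regulons(net_from(s, ["T0", "GB", "GA"]), ["T0"],
                                top_k=2, min_targets=1)
        assert regs[0].targets == ["GA", "GB"]  # lexicographic on ties

    def test_five_gene_toy_matches_hand_sort(self):
        genes = ["T0", "T1", "G2", "G3", "G4"]
        s = np.array([
            [0.0, 0.1, 0.9, 0.3, 0.5],
            [0.2, 0.0, 0.1, 0.8, 0.7],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0.0]])
        regs = extract_regulons(net_from(s, genes), ["T0", "T1"],
                                top_k=2, min_targets=1)
        by_tf = {r.tf: r.targets for r in regs}
        assert by_tf["T0"] == ["G2", "G4"]
        assert by_tf["T1"] == ["G3", "G4"]

    def test_min_targets_drops_small_regulons(self):
        s = np.random.default_rng(0).random((4, 4))
        regs = extract_regulons(net_from(s, ["T0", "G1", "G2", "G3"]),
                                ["T0"], top_k=3, min_targets=5)
        assert regs == []

    def test_no_tf_overlap_errors(self):
        s = np.zeros((2, 2))
        with pytest.raises(ValueError, match="TF"):
            extract_regulons(net_from(s, ["G0", "G1"]), ["TX"])


class TestPruneRegulons:
    class RejectBackend:
        def __init__(self, rejected):
            self.rejected = set(rejected)

        def verdicts(self, tf, targets):
            return [t for t in targets if t not in self.rejected]

    def regs(self):
        return [Regulon("T0", ["G1", "G2"], [0.9, 0.8]),
                Regulon("T1", ["G3"], [0.7])]

    def test_stub_returns_input_unchanged(self):
        regs = self.regs()
        out = prune_regulons(regs, PassThroughMotifBackend())
        assert [(r.tf, r.targets) for r in out] == \
            [(r.tf, r.targets) for r in regs]

    def test_mock_rejecting_one_target(self):
        out = prune_regulons(self.regs(), self.RejectBackend({"G2"}))
        assert out[0].targets == ["G1"]
        assert out[1].targets == ["G3"]

    def test_rejecting_all_targets_drops_regulon(self):
        out = prune_regulons(self.regs(), self.RejectBackend({"G3"}),
                             min_targets=1)
        assert [r.tf for r in out] == ["T0"]

    def test_backend_returning_unknown_target_errors(self):
        class Bad:
            def verdicts(self, tf, targets):
                return targets + ["GHOST"]

        with pytest.raises(ValueError, match="unknown"):
            prune_regulons(self.regs(), Bad())


class TestAUCell:
    def expr_with_ranks(self, order, n_spots=2):
        """Expression where `order[i]` is the gene at rank i+1."""
        m = len(order)
        values = np.zeros((m, n_spots))
        for rank, gene_idx in enumerate(order):
            values[gene_idx, :] = m - rank
        return ExpressionMatrix(values, [f"G{i}" for i in range(m)],
                                [f"S{j}" for j in range(n_spots)])

    def test_top_ranked_regulon_activity_one(self):
        expr = self.expr_with_ranks(list(range(10)))
        reg = Regulon("G0", ["G1"])  # genes at ranks 1 and 2
        act = aucell_activity(expr, [reg], threshold_frac=0.5)
        assert act.values[0, 0] == pytest.approx(1.0)

    def test_bottom_ranked_regulon_activity_zero(self):
        expr = self.expr_with_ranks(list(range(10)))
        reg = Regulon("G8", ["G9"])  # ranks 9, 10, below the 50% cutoff
        act = aucell_activity(expr, [reg], threshold_frac=0.5)
        assert act.values[0, 0] == pytest.approx(0.0)

    def test_recovery_curve_integral_matches_rank_walk(self):
        # regulon genes at ranks 1 and 4 of 10, threshold 0.5
        expr = self.expr_with_ranks([0, 2, 3, 1, 4, 5, 6, 7, 8, 9])
        reg = Regulon("G0", ["G1"])
        act = aucell_activity(expr, [reg], threshold_frac=0.5)
        hits = [1, 1, 1, 2, 2]          # members among top r, r = 1..5
        best = [1, 2, 2, 2, 2]          # best attainable
        assert act.values[0, 0] == pytest.approx(sum(hits) / sum(best))

    def test_monotone_transform_invariance(self, small_dataset):
        expr = small_dataset.expression
        reg = Regulon(expr.gene_ids[0], list(expr.gene_ids[1:4]))
        act1 = aucell_activity(expr, [reg])
        squashed = ExpressionMatrix(np.log1p(expr.values) ** 3,
                                    expr.gene_ids, expr.spot_ids)
        act2 = aucell_activity(squashed, [reg])
        np.testing.assert_allclose(act1.values, act2.values, atol=1e-12)

    def test_missing_genes_warn_zero_activity(self, tiny_expr):
        reg = Regulon("TX", ["TY", "TZ"])
        with pytest.warns(UserWarning, match="no genes"):
            act = aucell_activity(tiny_expr, [reg])
        assert (act.values == 0).all()

    def test_bad_threshold_errors(self, tiny_expr):
        with pytest.raises(ValueError, match="threshold"):
            aucell_activity(tiny_expr, [], threshold_frac=0.0)


class TestClusterSpots:
    def block_z(self, sizes, within=1.0, between=0.0, seed=0):
        n = sum(sizes)
        z = np.full((n, n), between)
        start = 0
        for s in sizes:
            z[start:start + s, start:start + s] = within
            start += s
        rng = np.random.default_rng(seed)
        return z + 0.01 * rng.random((n, n))

    def test_block_diagonal_recovers_blocks(self):
        z = self.block_z([10, 10, 10])
        labels = cluster_spots(z, seed=0, n_clusters=3)
        truth = np.repeat([0, 1, 2], 10)
        from spagnet import clustering_ari
        assert clustering_ari(labels, truth) == pytest.approx(1.0)

    def test_small_resolution_single_cluster(self):
        z = self.block_z([5, 5])
        labels = cluster_spots(z, resolution=1e-5, seed=0)
        assert labels.n_clusters == 1

    def test_same_seed_identical_labels(self):
        z = self.block_z([8, 8], within=0.8, between=0.2)
        a = cluster_spots(z, seed=3)
        b = cluster_spots(z, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_permutation_equivariance(self):
        z = self.block_z([6, 6, 6], within=0.9, between=0.05)
        labels = cluster_spots(z, seed=1, n_clusters=3).labels
        rng = np.random.default_rng(2)
        perm = rng.permutation(18)
        labels_p = cluster_spots(z[np.ix_(perm, perm)], seed=1,
                                 n_clusters=3).labels
        from spagnet import clustering_ari
        assert clustering_ari(labels_p, labels[perm]) == pytest.approx(1.0)

    def test_all_zero_graph_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            cluster_spots(np.zeros((4, 4)), seed=0)


class TestSpecificRegulons:
    def activity(self, rows, n_per_cluster=3):
        values = np.asarray(rows, dtype=float)
        return ActivityMatrix(values, [f"R{i}" for i in range(len(rows))],
                              [f"S{j}" for j in range(values.shape[1])])

    def labels(self, groups):
        return ClusterLabels(np.asarray(groups), resolution=1.0)

    def test_uniform_activity_filtered_out(self):
        act = self.activity([[0.5] * 6])
        table = specific_regulons(act, self.labels([0, 0, 0, 1, 1, 1]))
        assert not table["passed"].any()
        assert (table["log2fc"].abs() < 1e-9).all()

    def test_perfect_separation_auroc_one(self):
        act = self.activity([[1, 1, 1, 0, 0, 0]])
        table = specific_regulons(act, self.labels([0, 0, 0, 1, 1, 1]))
        row = table[(table.regulon == "R0") & (table.cluster == 0)].iloc[0]
        assert row.auroc == pytest.approx(1.0)
        assert row.passed

    def test_six_spot_toy_matches_hand_computation(self):
        act_vals = np.array([0.9, 0.8, 0.7, 0.2, 0.3, 0.1])
        act = self.activity([act_vals])
        lab = [0, 0, 0, 1, 1, 1]
        table = specific_regulons(act, self.labels(lab))
        row = table[(table.cluster == 0)].iloc[0]
        eps = 1e-9
        expected_fc = np.log2((act_vals[:3].mean() + eps)
                              / (act_vals[3:].mean() + eps))
        assert row.log2fc == pytest.approx(expected_fc, abs=1e-9)
        # exhaustive pairwise-rank AUROC
        wins = sum(a > b for a in act_vals[:3] for b in act_vals[3:])
        assert row.auroc == pytest.approx(wins / 9)

    def test_auroc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(0)
        vals = rng.random(14)
        lab = np.array([0] * 7 + [1] * 7)
        table = specific_regulons(self.activity([vals]), self.labels(lab),
                                  min_auroc=None)
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(vals[:7], vals[7:]).statistic
        row = table[table.cluster == 0].iloc[0]
        assert row.auroc == pytest.approx(u / 49, abs=1e-12)

    def test_singleton_cluster_flagged(self):
        act = self.activity([[0.9, 0.1, 0.2, 0.3]])
        table = specific_regulons(act, self.labels([0, 1, 1, 1]))
        row = table[table.cluster == 0].iloc[0]
        assert row.flagged
        assert np.isnan(row.auroc)

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="clusters"):
            specific_regulons(self.activity([[1, 2, 3]]),
                              self.labels([0, 0, 0]))

    def test_auroc_off_mode_uses_log2fc_only(self):
        # weak separation: fails AUROC>0.75 but passes log2FC>0.25
        act = self.activity([[0.9, 0.2, 0.8, 0.3, 0.25, 0.28]])
        lab = self.labels([0, 0, 0, 1, 1, 1])
        strict = specific_regulons(act, lab)
        loose = specific_regulons(act, lab, min_auroc=None)
        row_s = strict[strict.cluster == 0].iloc[0]
        row_l = loose[loose.cluster == 0].iloc[0]
        assert row_l.passed and row_l.log2fc > 0.25
        assert row_s.passed == (row_s.auroc > 0.75 and row_s.log2fc > 0.25)


def test_gmt_export_roundtrip(tmp_path):
    from spagnet.downstream import write_regulons_gmt

    regs = [Regulon("T0", ["G1", "G2"]), Regulon("T1", ["G3"])]
    path = tmp_path / "regs.gmt"
    write_regulons_gmt(regs, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["T0(+)", "T0", "G1", "G2"]
    assert lines[1].split("\t") == ["T1(+)", "T1", "G3"]
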