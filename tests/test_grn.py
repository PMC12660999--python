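"""TF->target scoring: distance-decay binding, additive interaction score,
pruning, metrics, influence, co-influence clustering, top targets."""

import numpy as np
import pandas as pd
import pytest

from plangrn import grn


def _binding_inputs(rows, acc, distances):
    hits = pd.DataFrame(rows, columns=["region_id", "motif_id", "count"])
    ocr2gene = pd.DataFrame(
        [(o, g, d) for (o, (g, d)) in distances.items()],
        columns=["ocr_id", "gene_id", "distance"],
    )
    return hits, pd.Series(acc), ocr2gene


class TestWeightedBinding:
    def test_zero_distance_passes_accessibility_through(self):
        hits, acc, o2g = _binding_inputs(
            [("o1", "M", 1)], {"o1": 2.0}, {"o1": ("g1", 0)}
        )
        B = grn.weighted_binding(hits, acc, o2g, {"tf": "M"})
        assert B.loc["tf", "g1"] == pytest.approx(2.0)

    def test_distance_equal_to_decay_length_gives_exp_minus_one(self):
        hits, acc, o2g = _binding_inputs(
            [("o1", "M", 1)], {"o1": 2.0}, {"o1": ("g1", 25_000)}
        )
        B = grn.weighted_binding(hits, acc, o2g, {"tf": "M"})
        assert B.loc["tf", "g1"] == pytest.approx(2 * np.exp(-1))

    def test_beyond_window_contributes_zero(self):
        hits, acc, o2g = _binding_inputs(
            [("o1", "M", 1)], {"o1": 5.0}, {"o1": ("g1", 150_000)}
        )
        B = grn.weighted_binding(hits, acc, o2g, {"tf": "M"})
        assert B.loc["tf", "g1"] == 0.0

    def test_multi_ocr_summation_oracle(self):
        rng = np.random.default_rng(0)
        distances, acc, rows = {}, {}, []
        expected = 0.0
        for k in range(8):
            d = int(rng.integers(-60_000, 60_000))
            a = float(rng.random() * 3)
            distances[f"o{k}"] = ("g1", d)
            acc[f"o{k}"] = a
            rows.append((f"o{k}", "M", 1))
            expected += a * np.exp(-abs(d) / 25_000)
        B = grn.weighted_binding(*_binding_inputs(rows, acc, distances), {"tf": "M"})
        assert B.loc["tf", "g1"] == pytest.approx(expected)

    def test_tf_without_motif_gets_zero_row(self):
        hits, acc, o2g = _binding_inputs(
            [("o1", "M", 1)], {"o1": 2.0}, {"o1": ("g1", 0)}
        )
        B = grn.weighted_binding(hits, acc, o2g, {"tf": "M", "naked": "NOMOTIF"})
        assert (B.loc["naked"] == 0).all()

    def test_invariant_to_uniform_accessibility_scaling(self):
        hits, acc, o2g = _binding_inputs(
            [("o1", "M", 1), ("o2", "M", 1)],
            {"o1": 1.0, "o2": 2.0},
            {"o1": ("g1", 100), "o2": ("g2", 5000)},
        )
        B1 = grn.weighted_binding(hits, acc, o2g, {"tf": "M"})
        B2 = grn.weighted_binding(hits, acc * 7.0, o2g, {"tf": "M"})
        np.testing.assert_allclose(B2.to_numpy(), 7.0 * B1.to_numpy())


class TestInteractionScores:
    def test_top_everything_scores_one(self):
        binding = pd.DataFrame(
            [[5.0, 1.0], [0.5, 0.1]], index=["tfA", "tfB"], columns=["g1", "g2"]
        )
        expr = pd.Series({"g1": 10.0, "g2": 1.0, "tfA": 9.0, "tfB": 0.5})
        net = grn.interaction_scores(binding, expr)
        top = net[(net["tf"] == "tfA") & (net["target"] == "g1")]["score"].iloc[0]
        assert top == pytest.approx(1.0)

    def test_bottom_everything_scores_zero(self):
        binding = pd.DataFrame(
            [[5.0, 1.0], [0.0, 0.0]], index=["tfA", "tfB"], columns=["g1", "g2"]
        )
        expr = pd.Series({"g1": 10.0, "g2": 0.0, "tfA": 9.0, "tfB": 0.0})
        net = grn.interaction_scores(binding, expr)
        bottom = net[(net["tf"] == "tfB") & (net["target"] == "g2")]["score"].iloc[0]
        assert bottom == pytest.approx(0.0)

    def test_matches_four_component_averaging_oracle(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(1)
        tfs, genes = ["t1", "t2", "t3"], ["g1", "g2", "g3", "g4"]
        binding = pd.DataFrame(rng.random((3, 4)), index=tfs, columns=genes)
        expr = pd.Series(rng.random(7), index=genes + tfs)

        def s01(x):
            r = rankdata(x)
            return (r - r.min()) / (r.max() - r.min())

        te = s01(expr[tfs].to_numpy())
        ge = s01(expr[genes].to_numpy())
        act = s01(binding.mean(axis=1).to_numpy())
        bnd = s01(binding.to_numpy().ravel()).reshape(3, 4)
        net = grn.interaction_scores(binding, expr).set_index(["tf", "target"])
        for i, t in enumerate(tfs):
            for j, g in enumerate(genes):
                expected = (te[i] + ge[j] + bnd[i, j] + act[i]) / 4
                assert net.loc[(t, g), "score"] == pytest.approx(expected)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(2)
        binding = pd.DataFrame(rng.random((5, 20)), index=[f"t{i}" for i in range(5)],
                               columns=[f"g{i}" for i in range(20)])
        expr = pd.Series(rng.random(25), index=list(binding.columns) + list(binding.index))
        net = grn.interaction_scores(binding, expr)
        assert net["score"].between(0, 1).all()


class TestPruneAndMetrics:
    def test_edge_exactly_at_threshold_excluded(self):
        net = pd.DataFrame(
            {"tf": ["a", "a"], "target": ["x", "y"], "score": [0.8, 0.81]}
        )
        g = grn.prune_network(net, 0.8)
        assert not g.has_edge("a", "x")
        assert g.has_edge("a", "y")

    def test_empty_result_allowed(self):
        net = pd.DataFrame({"tf": ["a"], "target": ["x"], "score": [0.1]})
        assert grn.prune_network(net).number_of_edges() == 0

    def test_star_graph_metrics(self):
        import networkx as nx

        g = nx.DiGraph()
        for k in range(5):
            g.add_edge("hub", f"t{k}", score=0.9)
        m = grn.network_metrics(g)
        assert m.loc["hub", "outdegree"] == 5
        assert m.loc["hub", "relative_outdegree"] == 1.0
        assert m.loc["t0", "relative_outdegree"] == 0.0  # sink
        assert grn.active_tfs(g) == 1

    def test_literal_relative_outdegree_flag(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edge("a", "b", score=1.0)
        g.add_edge("b", "c", score=1.0)
        default = grn.network_metrics(g)
        literal = grn.network_metrics(g, relative_outdegree_literal=True)
        assert default.loc["b", "relative_outdegree"] == 0.5
        assert literal.loc["b", "relative_outdegree"] == 0.5
        assert default.loc["a", "relative_outdegree"] == 1.0
        assert literal.loc["a", "relative_outdegree"] == 0.0

    def test_chain_centrality_matches_pagerank_oracle(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edge("a", "b", score=1.0)
        g.add_edge("b", "c", score=1.0)
        m = grn.network_metrics(g)
        pr = nx.pagerank(g, weight="score")
        for n in "abc":
            assert m.loc[n, "centrality"] == pytest.approx(pr[n])


class TestCentralitySimilarity:
    def test_identical_fates_correlate_perfectly(self):
        rng = np.random.default_rng(9)
        cent = pd.DataFrame({"f1": rng.random(10)})
        cent["f2"] = cent["f1"]
        cent["f3"] = rng.random(10)
        r, Z = grn.centrality_similarity(cent)
        assert r.loc["f1", "f2"] == pytest.approx(1.0)
        assert Z.shape == (2, 4)  # ward tree over three fates

    def test_matches_correlation_oracle(self):
        rng = np.random.default_rng(10)
        cent = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        r, _ = grn.centrality_similarity(cent)
        oracle = np.corrcoef(cent.to_numpy().T)
        np.testing.assert_allclose(r.to_numpy(), oracle, atol=1e-12)

    def test_supergroup_fates_cluster_together(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(11)
        base_a = rng.random(15)
        base_b = rng.random(15)
        cent = pd.DataFrame({
            "gutA": base_a + rng.normal(0, 0.05, 15),
            "gutB": base_a + rng.normal(0, 0.05, 15),
            "neuroA": base_b + rng.normal(0, 0.05, 15),
            "neuroB": base_b + rng.normal(0, 0.05, 15),
        })
        r, Z = grn.centrality_similarity(cent)
        labels = fcluster(Z, t=2, criterion="maxclust")
        by_fate = dict(zip(cent.columns, labels))
        assert by_fate["gutA"] == by_fate["gutB"]
        assert by_fate["neuroA"] == by_fate["neuroB"]
        assert by_fate["gutA"] != by_fate["neuroA"]


class TestInfluence:
    def _net(self):
        return pd.DataFrame({
            "tf": ["driver"] * 3 + ["bystander"] * 3,
            "target": ["g1", "g2", "g3"] * 2,
            "score": [0.95, 0.9, 0.85, 0.1, 0.15, 0.05],
        })

    def _dge(self):
        return pd.DataFrame(
            {"log2FC": [3.0, 2.5, 2.0, 1.5], "padj": [0.001, 0.001, 0.01, 0.2]},
            index=["g1", "g2", "g3", "driver"],
        )

    def test_planted_driver_ranks_first(self):
        infl = grn.influence_scores(self._net(), self._dge())
        assert infl.index[0] == "driver"

    def test_no_upregulated_degs_gives_zero_table(self):
        dge = self._dge()
        dge["padj"] = 1.0
        infl = grn.influence_scores(self._net(), dge)
        assert (infl["influence"] == 0).all()

    def test_ranking_invariant_to_doubling_log2fc(self):
        base = grn.influence_scores(self._net(), self._dge())
        dge2 = self._dge()
        dge2["log2FC"] *= 2
        doubled = grn.influence_scores(self._net(), dge2)
        assert list(base.index) == list(doubled.index)

    def test_tf_gene_mapping_feeds_expression_change(self):
        dge = self._dge()
        dge.loc["gene_of_driver"] = [4.0, 0.001]
        infl = grn.influence_scores(
            self._net(), dge, tf_gene={"driver": "gene_of_driver"}
        )
        assert infl.loc["driver", "expr_change"] == 4.0


class TestCoinfluence:
    def test_two_orthogonal_patterns_give_two_clusters(self):
        rng = np.random.default_rng(3)
        fates = [f"f{i}" for i in range(6)]
        rows = {}
        for k in range(4):
            rows[f"tA{k}"] = [1, 1, 1, 0, 0, 0] + rng.normal(0, 0.05, 6)
        for k in range(4):
            rows[f"tB{k}"] = [0, 0, 0, 1, 1, 1] + rng.normal(0, 0.05, 6)
        table = pd.DataFrame(rows, index=fates).T
        out = grn.coinfluence_clusters(table)
        a_clusters = set(out[out["tf"].str.startswith("tA")]["cluster"])
        b_clusters = set(out[out["tf"].str.startswith("tB")]["cluster"])
        assert len(a_clusters) == 1 and len(b_clusters) == 1
        assert a_clusters != b_clusters

    def test_single_tf_is_singleton(self):
        table = pd.DataFrame({"f1": [0.5], "f2": [0.1]}, index=["only"])
        out = grn.coinfluence_clusters(table)
        assert len(out) == 1 and out["rank_in_cluster"].iloc[0] == 1

    def test_top_five_flagged_by_centroid_correlation(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            rng.random((8, 5)) * 0.05 + np.array([1, 0, 1, 0, 1]),
            index=[f"t{i}" for i in range(8)],
        )
        out = grn.coinfluence_clusters(table, top_n=5)
        for _, grp in out.groupby("cluster"):
            assert grp["top"].sum() == min(5, len(grp))


class TestTopTargets:
    def test_hundred_targets_yield_five_at_quantile(self):
        net = pd.DataFrame({
            "tf": ["t"] * 100,
            "target": [f"g{i}" for i in range(100)],
            "score": np.linspace(0, 0.99, 100),
        })
        out = grn.top_targets(net, "t", quantile=0.95)
        assert len(out) == 5 or len(out) == 6  # interpolated quantile boundary

    def test_ties_at_threshold_kept(self):
        net = pd.DataFrame({
            "tf": ["t"] * 6,
            "target": list("abcdef"),
            "score": [0.9, 0.9, 0.9, 0.1, 0.1, 0.1],
        })
        out = grn.top_targets(net, "t", quantile=0.6)
        assert set(out["target"]) == {"a", "b", "c"}

    def test_unknown_tf_gives_empty_list(self):
        net = pd.DataFrame({"tf": ["t"], "target": ["g"], "score": [0.5]})
        assert grn.top_targets(net, "other").empty
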