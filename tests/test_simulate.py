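"""Synthetic-data generator: planted structure, determinism, null cases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, kruskal

from plangrn import simulate
from tests.conftest import small_config


def _group_means(acm, truth):
    """Brute-force per-type mean counts, the oracle for planted effects."""
    dense = np.asarray(acm.values.todense(), dtype=float)
    out = {}
    for ctype, grp in acm.obs.groupby("cluster"):
        cols = [acm.cell_ids.get_loc(c) for c in grp.index]
        out[ctype] = pd.Series(dense[:, cols].mean(axis=1), index=acm.feature_ids)
    return pd.DataFrame(out)


class TestExpression:
    def test_same_seed_bitwise_identical(self, small_cfg):
        a1, _ = simulate.generate_expression(small_cfg)
        a2, _ = simulate.generate_expression(small_cfg)
        assert (a1.values != a2.values).nnz == 0
        pd.testing.assert_frame_equal(a1.obs, a2.obs)

    def test_different_seed_changes_counts_not_structure(self, small_cfg, small_expression):
        a1, t1 = small_expression
        a2, t2 = simulate.generate_expression(small_config(seed=99))
        assert (a1.values != a2.values).nnz > 0
        assert t1.gene2module == t2.gene2module
        assert {m: len(v) for m, v in t1.module_members.items()} == {
            m: len(v) for m, v in t2.module_members.items()
        }

    def test_flat_fold_gives_exchangeable_type_means(self):
        cfg = small_config()
        specs = tuple(
            simulate.ModuleSpec(s.module_id, s.member_cell_types, s.n_genes, 1.0)
            for s in cfg.module_specs
        )
        cfg = simulate.SyntheticConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "module_specs": specs, "tf_profile_sigma": 0.0,
        })
        acm, truth = simulate.generate_expression(cfg)
        dense = np.asarray(acm.values.todense(), dtype=float)
        clusters = acm.obs["cluster"].to_numpy()
        rng = np.random.default_rng(5)
        pvals = []
        for i in rng.choice(acm.shape[0], 120, replace=False):
            groups = [dense[i, clusters == t] for t in cfg.cell_type_names]
            if all(g.sum() > 0 for g in groups):
                pvals.append(kruskal(*groups).pvalue)
        # under the null, Kruskal-Wallis p-values are ~uniform
        assert kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_group_mean_oracle_recovers_elevated_types(self):
        cfg = small_config()
        cfg = simulate.SyntheticConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "module_specs": (simulate.ModuleSpec("M1", ("muscle", "neurons"), 40, 8.0),),
            "n_tfs": 1,
        })
        acm, truth = simulate.generate_expression(cfg)
        gm = _group_means(acm, truth)
        members = truth.module_members["M1"]
        hits = 0
        for g in members:
            top2 = gm.loc[g].nlargest(2).index
            hits += set(top2) == {"muscle", "neurons"}
        assert hits / len(members) >= 0.95

    def test_rejects_gene_demand_exceeding_n_genes(self):
        with pytest.raises(ValueError, match="smaller than"):
            small_config().__class__(
                n_genes=10,
                module_specs=(simulate.ModuleSpec("M1", ("muscle",), 50, 8.0),),
            )

    def test_nb_marginal_moments(self, small_cfg, small_expression):
        # neutral genes in one type: mean m, var ~ m + d*m^2 (times libsize spread)
        acm, truth = small_expression
        dense = np.asarray(acm.values.todense(), dtype=float)
        clusters = acm.obs["cluster"].to_numpy()
        neutral = [g for g in acm.feature_ids if g not in truth.gene2module][:150]
        idx = [acm.feature_ids.get_loc(g) for g in neutral]
        sub = dense[np.ix_(idx, np.flatnonzero(clusters == "neoblast"))]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 1
        # implied dispersion from moments, pooled across genes
        implied = np.median((v[keep] - m[keep]) / m[keep] ** 2)
        # libsize log-normal sigma inflates the quadratic term
        expect = small_cfg.nb_dispersion + np.exp(small_cfg.libsize_sigma**2) - 1
        assert implied == pytest.approx(expect, rel=0.35)


class TestAccessibility:
    def test_zero_background_rate_means_only_planted_hits(self):
        cfg = small_config()
        cfg = simulate.SyntheticConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "background_motif_rate": 0.0,
        })
        acm, truth = simulate.generate_expression(cfg)
        _, ocrs, tss, hits = simulate.generate_accessibility(cfg, truth)
        planted_regions = set()
        for tf, mod in truth.tf2module.items():
            if mod is None:
                continue
            planted_regions |= {f"prom_{g}" for g in truth.module_members[mod]}
        planted_regions |= set(truth.ocr2module)
        assert set(hits["region_id"]) <= planted_regions

    def test_intervals_inside_genome_span(self, small_cfg, small_multiome):
        _, truth, _, ocrs, tss, _ = small_multiome
        for iv in (ocrs, tss):
            assert (iv.df["start"] >= 0).all()
            assert (iv.df["end"] <= small_cfg.genome_span).all()
            assert (iv.df["end"] > iv.df["start"]).all()

    def test_module_ocrs_open_by_configured_fold(self, small_cfg, small_multiome):
        _, truth, atac, _, _, _ = small_multiome
        gm = _group_means(atac, truth)
        specs = {s.module_id: s for s in small_cfg.module_specs}
        ratios = []
        for ocr, mod in truth.ocr2module.items():
            members = list(specs[mod].member_cell_types)
            others = [t for t in small_cfg.cell_type_names if t not in members]
            ratios.append(gm.loc[ocr, members].mean() / max(gm.loc[ocr, others].mean(), 1e-9))
        assert np.median(ratios) == pytest.approx(small_cfg.ocr_fold_elevation, rel=0.3)

    def test_ocr_maps_to_nearest_gene_by_construction(self, small_multiome):
        _, truth, _, ocrs, tss, _ = small_multiome
        o2g = truth.ocr2gene.set_index("ocr_id")
        tss_pos = tss.df.set_index("id")["start"]
        window = small_config().ocr_tss_window + small_config().ocr_width
        for _, row in ocrs.df.sample(30, random_state=0).iterrows():
            gene = o2g.loc[row["id"], "gene_id"]
            assert abs(tss_pos[gene] - row["start"]) <= window

    def test_rejects_too_small_genome(self, small_cfg, small_expression):
        _, truth = small_expression
        cfg = simulate.SyntheticConfig(**{
            **{f: getattr(small_cfg, f) for f in small_cfg.__dataclass_fields__},
            "genome_span": 100_000,
        })
        with pytest.raises(ValueError, match="too small"):
            simulate.generate_accessibility(cfg, truth)


class TestKnockdown:
    def test_null_knockdown_is_exchangeable(self):
        cfg = small_config()
        cfg = simulate.SyntheticConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "knockdown_spec": simulate.KnockdownSpec(
                "TF03", ("phagocytes", "parenchyma"), 1.0, 0.0, 2
            ),
        })
        acm, truth = simulate.generate_expression(cfg)
        kd = simulate.generate_knockdown(cfg, truth)
        sizes = kd.obs.groupby(["condition", "cluster"]).size().unstack()
        assert (sizes.loc["control"] == sizes.loc["knockdown"]).all()
        gm = kd.obs.groupby("condition").size()
        dense = np.asarray(kd.values.todense(), dtype=float)
        cond = kd.obs["condition"].to_numpy()
        targets = [kd.feature_ids.get_loc(g) for g in truth.tf2targets["TF03"]]
        r = dense[np.ix_(targets, cond == "knockdown")].mean() / dense[
            np.ix_(targets, cond == "control")
        ].mean()
        assert r == pytest.approx(1.0, rel=0.1)

    def test_target_suppression_ratio_in_affected_types_only(self, small_cfg, small_expression):
        _, truth = small_expression
        kd = simulate.generate_knockdown(small_cfg, truth)
        dense = np.asarray(kd.values.todense(), dtype=float)
        obs = kd.obs.reset_index()
        targets = [kd.feature_ids.get_loc(g) for g in truth.tf2targets["TF03"]]
        def mean_of(cluster, condition):
            cols = obs.index[(obs["cluster"] == cluster) & (obs["condition"] == condition)]
            return dense[np.ix_(targets, cols)].mean()
        for affected in ("phagocytes", "parenchyma"):
            r = mean_of(affected, "knockdown") / mean_of(affected, "control")
            assert r == pytest.approx(0.3, abs=0.08)
        # unaffected types pooled (target genes are depleted there, so the
        # per-type ratio is noisy; the pooled ratio should stay at 1)
        unaffected = obs["cluster"].isin(["phagocytes", "parenchyma"]) == False  # noqa: E712
        cols_kd = obs.index[unaffected & (obs["condition"] == "knockdown")]
        cols_ct = obs.index[unaffected & (obs["condition"] == "control")]
        r_other = dense[np.ix_(targets, cols_kd)].mean() / dense[np.ix_(targets, cols_ct)].mean()
        assert r_other == pytest.approx(1.0, rel=0.12)

    def test_abundance_reduction_halves_affected_clusters(self, small_cfg, small_expression):
        _, truth = small_expression
        kd = simulate.generate_knockdown(small_cfg, truth)
        sizes = kd.obs.groupby(["condition", "cluster"]).size().unstack()
        for affected in ("phagocytes", "parenchyma"):
            ratio = sizes.loc["knockdown", affected] / sizes.loc["control", affected]
            assert ratio == pytest.approx(0.5, abs=0.05)
        assert sizes.loc["knockdown", "muscle"] == sizes.loc["control", "muscle"]
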