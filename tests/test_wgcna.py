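"""Co-expression modules: CV filter, soft power, TOM, tree cut, tau,
classification and TF connectivity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plangrn import wgcna


class TestCvFilter:
    def test_constant_row_removed(self):
        m = pd.DataFrame([[5.0] * 10, [1.0] + [0.0] * 9], index=["flat", "hot"])
        out = wgcna.filter_by_cv(m, 1.25)
        assert list(out.index) == ["hot"]

    def test_one_hot_cv_is_three_for_ten_groups(self):
        x = np.zeros(10)
        x[0] = 7.0
        cv = x.std(ddof=0) / x.mean()
        assert cv == pytest.approx(3.0)
        m = pd.DataFrame([x], index=["hot"])
        assert len(wgcna.filter_by_cv(m, 1.25)) == 1

    def test_zero_threshold_keeps_all_positive_rows(self):
        m = pd.DataFrame([[1.0] * 5, [2.0, 1, 1, 1, 1]], index=["a", "b"])
        assert len(wgcna.filter_by_cv(m, 0.0)) == 1  # flat row has CV 0, kept only if > 0
        assert len(wgcna.filter_by_cv(m, -0.1)) == 2


class TestSoftPower:
    def test_mean_connectivity_non_increasing_in_power(self):
        rng = np.random.default_rng(0)
        x = rng.random((30, 10))
        cor = np.abs(np.corrcoef(x))
        table, _ = wgcna.soft_power_scan(cor, powers=range(1, 10))
        mk = table["mean_k"].to_numpy()
        assert (np.diff(mk) <= 1e-9).all()

    def test_identity_correlation_flagged_degenerate(self):
        table, _ = wgcna.soft_power_scan(np.eye(20), powers=range(1, 4))
        assert table["r2"].isna().all()

    def test_smallest_power_reaching_target_is_chosen(self):
        # heavy-tailed planted connectivity: u_i u_j adjacency is scale-free
        rng = np.random.default_rng(1)
        u = rng.pareto(2.0, 150) + 0.05
        u = np.clip(u / u.max(), 0.05, 1.0)
        beta0 = 6
        cor = np.outer(u, u) ** (1.0 / beta0)
        np.fill_diagonal(cor, 1.0)
        table, chosen = wgcna.soft_power_scan(cor, r2_target=0.8)
        ok = table.dropna(subset=["r2"])
        reaching = ok.loc[ok["r2"] >= 0.8, "power"]
        if len(reaching):
            assert chosen == reaching.iloc[0]
        else:
            assert chosen == int(ok.loc[ok["r2"].idxmax(), "power"])


class TestTom:
    def test_disjoint_cliques_give_block_tom(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        t = wgcna.tom(a).to_numpy()
        assert np.allclose(t[:3, :3], 1.0)
        assert np.allclose(t[:3, 3:], 0.0)

    def test_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = wgcna.tom(a).to_numpy()
        n = a.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert t[i, j] == 1.0
                    continue
                L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected = (L + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        a = rng.random((12, 12)) * 0.9
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = wgcna.tom(a).to_numpy()
        assert (t >= 0).all() and (t <= 1).all()

    def test_rejects_asymmetric_input(self):
        a = np.eye(4)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            wgcna.tom(a)


def _planted_tom(rng, sizes=(60, 60), within=0.9):
    """Block TOM-like similarity with noise, for tree-cut tests."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    base = np.where(labels[:, None] == labels[None, :], within, 0.05)
    noise = rng.normal(0, 0.01, (n, n))
    noise = (noise + noise.T) / 2
    t = np.clip(base + noise, 0, 1)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=[f"f{i}" for i in range(n)],
                        columns=[f"f{i}" for i in range(n)]), labels


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(4)
        tom_m, labels = _planted_tom(rng)
        params = wgcna.WGCNAParams(min_module_size=50)
        assignment = wgcna.detect_modules(tom_m, params)
        pred = assignment.table["module"]
        assert adjusted_rand_score(labels, pred) == 1.0
        assert len(assignment.module_members) == 2

    def test_min_size_above_n_gives_no_modules(self):
        rng = np.random.default_rng(5)
        tom_m, _ = _planted_tom(rng, sizes=(20, 20))
        params = wgcna.WGCNAParams(min_module_size=100)
        assignment = wgcna.detect_modules(tom_m, params)
        assert (assignment.table["module"] == "unassigned").all()

    def test_assignment_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(6)
        tom_m, _ = _planted_tom(rng)
        perm = rng.permutation(len(tom_m))
        shuffled = tom_m.iloc[perm, perm]
        params = wgcna.WGCNAParams(min_module_size=50)
        a1 = wgcna.detect_modules(tom_m, params).table["module"]
        a2 = wgcna.detect_modules(shuffled, params).table["module"]
        # same partition up to module-name permutation
        joint = pd.crosstab(a1[shuffled.index], a2)
        assert ((joint > 0).sum(axis=1) == 1).all()


class TestProfilesAndTau:
    def test_relative_profile_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.random((10, 4)) + 0.1, index=[f"g{i}" for i in range(10)])
        assignment = wgcna.ModuleAssignment(
            table=pd.DataFrame({"module": ["m1"] * 10}, index=mat.index),
            module_members={"m1": list(mat.index)},
        )
        avg, rel = wgcna.module_profiles(assignment, mat)
        assert rel.sum(axis=1).to_numpy() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(avg.loc["m1"], mat.mean(axis=0))

    def test_single_group_relative_profile_is_one(self):
        mat = pd.DataFrame({"only": [3.0, 5.0]}, index=["g0", "g1"])
        assignment = wgcna.ModuleAssignment(
            table=pd.DataFrame({"module": ["m1", "m1"]}, index=mat.index),
            module_members={"m1": ["g0", "g1"]},
        )
        _, rel = wgcna.module_profiles(assignment, mat)
        assert rel.loc["m1", "only"] == 1.0

    @pytest.mark.parametrize(
        "profile,expected",
        [([1.0, 1.0, 1.0], 0.0), ([1.0, 0.0, 0.0], 1.0), ([1.0, 0.5, 0.0], 0.75)],
    )
    def test_tau_closed_form(self, profile, expected):
        assert wgcna.tau(np.array(profile)) == pytest.approx(expected)

    def test_tau_bounds_on_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.random(rng.integers(2, 12))
            assert 0.0 <= wgcna.tau(x) <= 1.0

    def test_tau_rejects_degenerate_profiles(self):
        with pytest.raises(ValueError):
            wgcna.tau(np.zeros(5))
        with pytest.raises(ValueError):
            wgcna.tau(np.array([-1.0, 2.0]))


class TestClassification:
    def _assignment(self, gene_matrix, members):
        return wgcna.ModuleAssignment(
            table=pd.DataFrame({"module": ["m"] * len(members)}, index=members),
            module_members={"m": members},
        )

    def test_single_peak_classified_specific(self):
        rng = np.random.default_rng(9)
        groups = [f"t{j}" for j in range(10)]
        genes = [f"g{i}" for i in range(20)]
        mat = pd.DataFrame(rng.random((20, 10)) * 0.1, index=genes, columns=groups)
        mat["t3"] += 8.0
        out = wgcna.classify_modules(self._assignment(mat, genes), mat, prefix="E")
        row = out.table.iloc[0]
        assert row["cls"] == "s" and row["peak_group"] == "t3"
        assert row["module"] == "sE01"

    def test_two_peaks_classified_mixed(self):
        rng = np.random.default_rng(10)
        groups = [f"t{j}" for j in range(10)]
        genes = [f"g{i}" for i in range(20)]
        mat = pd.DataFrame(rng.random((20, 10)) * 0.1, index=genes, columns=groups)
        mat["t2"] += 8.0
        mat["t5"] += 8.0
        out = wgcna.classify_modules(self._assignment(mat, genes), mat, prefix="E")
        assert out.table.iloc[0]["cls"] == "m"

    def test_flat_profile_classified_mixed(self):
        # no group exceeds mean + 1.5 sd on a flat profile: zero outliers -> m
        rng = np.random.default_rng(11)
        groups = [f"t{j}" for j in range(10)]
        genes = [f"g{i}" for i in range(20)]
        mat = pd.DataFrame(1.0 + rng.random((20, 10)) * 0.01, index=genes, columns=groups)
        out = wgcna.classify_modules(self._assignment(mat, genes), mat, prefix="E")
        assert out.table.iloc[0]["cls"] == "m"

    def test_ordering_by_peak_group_position(self):
        rng = np.random.default_rng(12)
        groups = [f"t{j}" for j in range(6)]
        mat = pd.DataFrame(rng.random((40, 6)) * 0.1,
                           index=[f"g{i}" for i in range(40)], columns=groups)
        mat.iloc[:20, 4] += 5.0  # first module peaks at t4
        mat.iloc[20:, 1] += 5.0  # second module peaks at t1
        assignment = wgcna.ModuleAssignment(
            table=pd.DataFrame({"module": ["a"] * 20 + ["b"] * 20}, index=mat.index),
            module_members={"a": list(mat.index[:20]), "b": list(mat.index[20:])},
        )
        out = wgcna.classify_modules(assignment, mat, prefix="E")
        name_of = out.table["module"]
        assert name_of.iloc[20] == "sE01"  # t1 peak ordered first
        assert name_of.iloc[0] == "sE02"


class TestConnectivity:
    def test_exact_profile_gives_unit_correlation(self):
        avg = pd.DataFrame([[1.0, 2, 3, 4]], index=["m1"])
        tf = pd.DataFrame([[2.0, 4, 6, 8], [4.0, 3, 2, 1]], index=["tf1", "tf2"])
        conn = wgcna.tf_connectivity(tf, avg)
        assert conn.loc["tf1", "m1"] == pytest.approx(1.0)
        assert conn.loc["tf2", "m1"] == pytest.approx(-1.0)

    def test_constant_profile_gives_nan(self):
        avg = pd.DataFrame([[1.0, 2, 3]], index=["m1"])
        tf = pd.DataFrame([[5.0, 5, 5]], index=["tf1"])
        assert np.isnan(wgcna.tf_connectivity(tf, avg).loc["tf1", "m1"])

    def test_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(13)
        tf = pd.DataFrame(rng.random((5, 8)), index=[f"tf{i}" for i in range(5)])
        avg = pd.DataFrame(rng.random((3, 8)), index=[f"m{i}" for i in range(3)])
        conn = wgcna.tf_connectivity(tf, avg)
        for t in tf.index:
            for m in avg.index:
                assert conn.loc[t, m] == pytest.approx(
                    np.corrcoef(tf.loc[t], avg.loc[m])[0, 1]
                )
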