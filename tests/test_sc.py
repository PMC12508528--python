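"""Single-cell QC, module scores, stratification and statistics."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import stats

from sig2screen import sc
from sig2screen.ranking import Signature


def _adata(X, genes=None, mito=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    ad = AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    ad.var["mito"] = mito if mito is not None else [False] * X.shape[1]
    return ad


class TestFilterCells:
    def _qc_data(self):
        rng = np.random.default_rng(0)
        n_genes = 600
        X = rng.poisson(2.0, size=(3, n_genes)).astype(float)
        X[X == 0] = 1  # every gene detected
        # cell 0: only 150 detected genes
        X[0, 150:] = 0
        # cell 1: 35% mitochondrial counts
        mito = np.zeros(n_genes, dtype=bool)
        mito[:10] = True
        X[1, :] = 1.0
        X[1, :10] = 0.35 * (n_genes - 10) / (1 - 0.35) / 10
        return _adata(X, mito=list(mito))

    def test_low_gene_and_high_mito_cells_excluded(self):
        ad = self._qc_data()
        kept, report = sc.filter_cells(ad, min_genes=200, max_mito_frac=0.30)
        assert list(kept.obs_names) == ["c2"]
        assert report["dropped_low_genes"] == 1
        assert report["dropped_high_mito"] == 1

    def test_idempotent(self):
        ad = self._qc_data()
        once, _ = sc.filter_cells(ad)
        twice, rep = sc.filter_cells(once)
        assert rep["kept"] == once.n_obs
        assert list(twice.obs_names) == list(once.obs_names)

    def test_all_dropped_errors(self):
        ad = _adata(np.ones((2, 10)))
        with pytest.raises(ValueError, match="all cells dropped"):
            sc.filter_cells(ad, min_genes=200)


class TestLognormalize:
    def test_single_gene_cell(self):
        ad = _adata([[7, 0], [1, 1]])
        sc.lognormalize(ad, scale=1e4)
        assert ad.layers["lognorm"][0, 0] == pytest.approx(np.log1p(1e4))

    def test_proportional_cells_identical(self):
        ad = _adata([[1, 2, 3], [2, 4, 6]])
        sc.lognormalize(ad)
        np.testing.assert_allclose(ad.layers["lognorm"][0], ad.layers["lognorm"][1])

    def test_row_sums_equal_scale(self):
        rng = np.random.default_rng(1)
        ad = _adata(rng.poisson(5, size=(20, 30)) + 1)
        sc.lognormalize(ad, scale=1e4)
        sums = np.expm1(ad.layers["lognorm"]).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-8)

    def test_zero_total_cell_errors(self):
        ad = _adata([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero-total"):
            sc.lognormalize(ad)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        ad = _adata(np.full((30, 200), 4.0))
        ad.layers["lognorm"] = np.asarray(ad.X).copy()
        score = sc.module_score(ad, ["g1", "g5", "g7"], nbin=5, nctrl=20, seed=0)
        np.testing.assert_allclose(score, 0.0)

    def test_spiked_cells_score_higher(self):
        rng = np.random.default_rng(2)
        n, g = 400, 500
        L = rng.normal(1.0, 0.3, size=(n, g))
        sig_genes = [f"g{i}" for i in range(5)]
        L[: n // 2, :5] += 2.0  # spike the signature in half the cells
        ad = _adata(np.exp(L))
        ad.layers["lognorm"] = L
        score = sc.module_score(ad, sig_genes, seed=0)
        res = stats.mannwhitneyu(score[: n // 2], score[n // 2 :], alternative="greater")
        assert res.pvalue < 0.01

    def test_deterministic_and_seed_sensitivity(self):
        rng = np.random.default_rng(3)
        L = rng.normal(0, 1, size=(100, 400))
        ad = _adata(np.exp(L))
        ad.layers["lognorm"] = L
        genes = [f"g{i}" for i in range(10)]
        s1 = sc.module_score(ad, genes, seed=7)
        s2 = sc.module_score(ad, genes, seed=7)
        pd.testing.assert_series_equal(s1, s2)
        s3 = sc.module_score(ad, genes, seed=8)
        assert np.abs(s1 - s3).mean() < 0.1 * s1.std() + 1e-9

    def test_null_centering_random_signatures(self):
        """Random gene sets on unstructured data score ~0 on average."""
        rng = np.random.default_rng(4)
        L = rng.normal(0, 1, size=(200, 600))
        ad = _adata(np.exp(L))
        ad.layers["lognorm"] = L
        means = []
        for k in range(100):
            genes = [f"g{i}" for i in rng.choice(600, size=10, replace=False)]
            means.append(sc.module_score(ad, genes, seed=k).mean())
        assert abs(np.mean(means)) < 0.05

    def test_missing_genes_named(self):
        ad = _adata(np.ones((5, 10)))
        ad.layers["lognorm"] = np.asarray(ad.X)
        with pytest.raises(ValueError, match="nope"):
            sc.module_score(ad, ["nope"], seed=0)


class TestStratify:
    def test_median_split(self):
        out = sc.stratify(pd.Series([1, 2, 3, 4]))
        assert list(out) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        out = sc.stratify(pd.Series([1, 2, 2, 3]))
        assert list(out) == ["low", "low", "low", "high"]

    def test_threshold_rule(self):
        out = sc.stratify(pd.Series([-1.0, 1.0]), rule="threshold", threshold=0.0)
        assert list(out) == ["low", "high"]

    def test_constant_scores_suggest_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            sc.stratify(pd.Series([2.0, 2.0, 2.0]))


class TestCompositionTest:
    def test_identical_composition_null(self):
        labels = pd.Series(["high"] * 20 + ["low"] * 20)
        types = pd.Series((["T", "MDSC"] * 10) * 2)
        res = sc.composition_test(labels, types)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_2x2_table(self):
        """[[10,20],[20,10]]: E=15 everywhere, chi2 = 4*25/15 = 6.667."""
        labels = pd.Series(["a"] * 30 + ["b"] * 30)
        types = pd.Series(["x"] * 10 + ["y"] * 20 + ["x"] * 20 + ["y"] * 10)
        res = sc.composition_test(labels, types)
        assert res["chi2"] == pytest.approx(6.667, abs=1e-3)
        assert res["df"] == 1

    def test_proportions_sum_to_one(self, sc_pair):
        _, query, _ = sc_pair
        labels = pd.Series(
            np.where(np.arange(query.n_obs) % 2 == 0, "high", "low"), index=query.obs_names
        )
        res = sc.composition_test(labels, query.obs["true_type"])
        np.testing.assert_allclose(res["proportions"].sum(axis=1), 1.0, atol=1e-12)


class TestGroupCompare:
    def test_exact_small_sample_enumeration(self):
        """{1,2} vs {3,4}: U=0, exact two-sided p = 2/6."""
        vals = pd.Series([1.0, 2.0, 3.0, 4.0])
        labels = pd.Series(["high", "high", "low", "low"])
        res = sc.group_compare(vals, labels)
        assert res["U"] == 0
        assert res["p_value"] == pytest.approx(1 / 3)
        assert res["method"] == "exact"

    def test_identical_groups_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = pd.Series(["high"] * 3 + ["low"] * 3)
        assert sc.group_compare(vals, labels)["p_value"] == pytest.approx(1.0)

    def test_auc_identity_with_roc(self):
        from sig2screen.outcomes import roc_auc

        rng = np.random.default_rng(5)
        vals = pd.Series(rng.normal(0, 1, 60))
        labels = pd.Series(np.where(rng.random(60) < 0.5, "high", "low"))
        res = sc.group_compare(vals, labels)
        auc = roc_auc(vals, (labels == "high").astype(int)).auc
        assert res["auc"] == pytest.approx(auc)

    def test_exact_and_asymptotic_agree_at_crossover(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.5, 1, 8)
        y = rng.normal(0.0, 1, 8)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_asym = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01


class TestCorrelate:
    def test_linear_pearson_one(self):
        x = np.arange(10.0)
        assert sc.correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r_s, _ = sc.correlate(x, x**3, method="spearman")
        r_p, _ = sc.correlate(x, x**3, method="pearson")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_rank_formula_hand_example(self):
        """x=(1,2,3), y=(3,1,2): rho = 1 - 6*6/(3*8) = -0.5."""
        r, _ = sc.correlate([1, 2, 3], [3, 1, 2], method="spearman")
        assert r == pytest.approx(-0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sc.correlate([1, 1, 1], [1, 2, 3])


class TestPatientAggregate:
    def _cohort(self):
        L = np.array([[1.0, 0.0], [3.0, 0.0], [5.0, 2.0]])
        ad = _adata(np.exp(L), genes=["CXCL1", "CXCL2"])
        ad.layers["lognorm"] = L
        ad.obs["patient"] = ["p1", "p1", "p2"]
        return ad

    def test_mean_over_cells(self):
        out = sc.patient_aggregate(self._cohort(), ["CXCL1"])
        assert out["p1"] == pytest.approx(2.0)

    def test_subset_drop_warns(self):
        ad = self._cohort()
        subset = pd.Series([True, True, False], index=ad.obs_names)
        with pytest.warns(UserWarning, match="p2"):
            out = sc.patient_aggregate(ad, ["CXCL1"], subset)
        assert "p2" not in out.index

    def test_cell_order_invariance(self):
        ad = self._cohort()
        perm = ad[[2, 0, 1]].copy()
        pd.testing.assert_series_equal(
            sc.patient_aggregate(ad, ["CXCL1", "CXCL2"]),
            sc.patient_aggregate(perm, ["CXCL1", "CXCL2"]),
        )


class TestSpotCoexpression:
    def test_labels_and_fraction(self):
        spots = pd.DataFrame({"A": [1, 0, 2, 0], "B": [1, 1, 0, 0]})
        res = sc.spot_coexpression(spots, "A", "B")
        assert list(res["labels"]) == ["both", "b_only", "a_only", "none"]
        assert res["fraction_both"] == pytest.approx(0.25)

    def test_edge_fractions(self):
        spots = pd.DataFrame({"A": [0, 0], "B": [1, 1]})
        assert sc.spot_coexpression(spots, "A", "B")["fraction_both"] == 0.0
        spots2 = pd.DataFrame({"A": [1, 2], "B": [1, 1]})
        assert sc.spot_coexpression(spots2, "A", "B")["fraction_both"] == 1.0

    def test_absent_gene(self):
        with pytest.raises(KeyError, match="C"):
            sc.spot_coexpression(pd.DataFrame({"A": [1]}), "A", "C")
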