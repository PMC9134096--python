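"""Association GLM, permutation threshold, Harrell-Davis quantile, GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats
from scipy.stats.mstats import hdquantiles

from dysbioscan.association import (
    AssociationResult,
    PermutationThreshold,
    assoc_glm,
    enrichment_score,
    gsea_effect_ranked,
    hd_quantile,
    min_p_permutation,
    pca_covariates,
    threshold_with_ci,
)
from dysbioscan.tables import GeneSetCollection


class TestPcaCovariates:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=8)
        X = np.outer(v, u)  # features x samples
        scores = pca_covariates(X, 2)
        total_var = ((X.T - X.T.mean(0)) ** 2).sum()
        pc1_var = (scores[:, 0] ** 2).sum()
        assert pc1_var / total_var >= 1 - 1e-9

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(12, 9))
        scores = pca_covariates(X, 4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 8))  # features x samples
        scores = pca_covariates(X, 3)
        xc = X.T - X.T.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        oracle = xc @ v[:, order[:3]]
        for k in range(3):  # eigenvectors are sign-ambiguous
            a, b = scores[:, k], oracle[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            pca_covariates(rng.normal(size=(5, 4)), 4)


class TestAssocGlm:
    def test_constant_feature_null(self):
        X = np.ones((10, 1))
        y = np.r_[np.zeros(5), np.ones(5)]
        res = assoc_glm(X, y)
        assert res.table["beta"].iloc[0] == pytest.approx(0.0)
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_two_group_beta_is_mean_difference(self):
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        res = assoc_glm(X, y)
        assert res.table["beta"].iloc[0] == pytest.approx(6.0)

    def test_matches_normal_equations_oracle(self, rng):
        n, m, c = 30, 12, 3
        X = rng.normal(size=(n, m))
        y = np.r_[np.zeros(15), np.ones(15)]
        covs = rng.normal(size=(n, c))
        res = assoc_glm(X, y, covariates=covs)
        design = np.column_stack([np.ones(n), y, covs])
        xtx_inv = np.linalg.inv(design.T @ design)
        for j in range(m):
            beta_hat = xtx_inv @ design.T @ X[:, j]
            resid = X[:, j] - design @ beta_hat
            sigma2 = resid @ resid / (n - design.shape[1])
            se = np.sqrt(sigma2 * xtx_inv[1, 1])
            assert res.table["beta"].iloc[j] == pytest.approx(beta_hat[1], abs=1e-9)
            assert res.table["se"].iloc[j] == pytest.approx(se, abs=1e-9)
            t = beta_hat[1] / se
            p = 2 * stats.t.sf(abs(t), n - design.shape[1])
            assert res.table["p_value"].iloc[j] == pytest.approx(p, abs=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 24
        X = rng.normal(size=(n, 4))
        y = rng.integers(0, 2, size=n).astype(float)
        y[:3], y[-3:] = 0, 1  # both classes present
        covs = rng.normal(size=(n, 2))
        res = assoc_glm(X, y, covariates=covs)
        design = sm.add_constant(np.column_stack([y, covs]))
        for j in range(4):
            fit = sm.OLS(X[:, j], design).fit()
            assert res.table["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.table["p_value"].iloc[j] == pytest.approx(
                fit.pvalues[1], abs=1e-10
            )

    def test_collinear_design_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ValueError, match="rank-deficient"):
            assoc_glm(X, y, covariates=np.column_stack([y, y]))

    def test_confounded_covariate_adjustment(self):
        """Age drives abundance and differs between groups: the adjusted
        model stays calibrated, the unadjusted model inflates type I."""
        g = np.random.default_rng(207)
        n1 = n2 = 40
        labels = np.r_[np.zeros(n1), np.ones(n2)]
        rej_adj = rej_un = total = 0
        for _ in range(40):
            age = g.normal(45, 10, n1 + n2) + 10 * labels
            X = 0.08 * age[:, None] + g.standard_normal((n1 + n2, 30))
            adj = assoc_glm(X, labels, covariates=age[:, None])
            un = assoc_glm(X, labels)
            rej_adj += int((adj.table["p_value"] < 0.05).sum())
            rej_un += int((un.table["p_value"] < 0.05).sum())
            total += 30
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rej_adj / total - 0.05) < 4 * se
        assert rej_un / total > 0.25


class TestHdQuantile:
    def test_constant_vector(self):
        assert hd_quantile([3.0] * 7, 0.5) == pytest.approx(3.0)

    def test_large_sample_consistency(self):
        u = np.random.default_rng(1).uniform(size=10_000)
        assert hd_quantile(u, 0.95) == pytest.approx(0.95, abs=0.01)

    @given(st.integers(2, 200), st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=60)
    def test_weights_telescope_to_one(self, n, q):
        a, b = (n + 1) * q, (n + 1) * (1 - q)
        w = np.diff(special.betainc(a, b, np.arange(n + 1) / n))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # and the estimator equals the weighted order statistics directly
        x = np.sort(np.random.default_rng(n).normal(size=n))
        assert hd_quantile(x, q) == pytest.approx(float(w @ x), abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(size=73)
        for q in (0.1, 0.5, 0.95):
            ref = float(hdquantiles(x, prob=[q])[0])
            assert hd_quantile(x, q) == pytest.approx(ref, abs=1e-10)

    def test_monotone_in_q_and_affine_equivariant(self, rng):
        x = rng.normal(size=50)
        qs = np.linspace(0.05, 0.95, 10)
        vals = [hd_quantile(x, q) for q in qs]
        assert (np.diff(vals) >= -1e-12).all()
        shifted = [hd_quantile(3 * x + 2, q) for q in qs]
        np.testing.assert_allclose(shifted, 3 * np.array(vals) + 2, atol=1e-10)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2])
    def test_invalid_q(self, q):
        with pytest.raises(ValueError):
            hd_quantile([1.0, 2.0], q)


class TestMinPPermutation:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.r_[np.zeros(15), np.ones(15)]
        a = min_p_permutation(X, y, n_iter=200, seed=9)
        b = min_p_permutation(X, y, n_iter=200, seed=9)
        np.testing.assert_array_equal(a.min_p, b.min_p)

    def test_single_feature_threshold_near_uniform_quantile(self):
        """One null feature: min P is U(0,1), so the HD 95th percentile of
        -log10(P_min) sits near -log10(0.05) = 1.301."""
        g = np.random.default_rng(5)
        X = g.standard_normal((83, 1))
        y = np.r_[np.zeros(40), np.ones(43)]
        null = min_p_permutation(X, y, n_iter=4000, seed=11)
        est = hd_quantile(-np.log10(null.min_p), 0.95)
        assert est == pytest.approx(-np.log10(0.05), abs=0.12)

    @pytest.mark.parametrize("m", [10, 50])
    def test_sidak_closed_form(self, m):
        """m independent null features: -log10 P_sig ~ -log10(1-0.95^(1/m))."""
        g = np.random.default_rng(m)
        X = g.standard_normal((83, m))
        y = np.r_[np.zeros(40), np.ones(43)]
        null = min_p_permutation(X, y, n_iter=4000, seed=m)
        est = hd_quantile(-np.log10(null.min_p), 0.95)
        expected = -np.log10(1 - 0.95 ** (1 / m))
        assert est == pytest.approx(expected, abs=0.15)

    def test_small_n_iter_warns(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.r_[np.zeros(6), np.ones(6)]
        with pytest.warns(UserWarning, match="unstable"):
            min_p_permutation(X, y, n_iter=50, seed=0)


class TestThresholdCI:
    def test_ci_brackets_point(self, rng):
        X = rng.normal(size=(40, 8))
        y = np.r_[np.zeros(20), np.ones(20)]
        null = min_p_permutation(X, y, n_iter=500, seed=2)
        est = threshold_with_ci(null, n_boot=300, seed=3)
        assert est.ci_low <= est.neg_log10_p_sig <= est.ci_high

    def test_degenerate_null_zero_width(self):
        from dysbioscan.association import PermutationNull

        null = PermutationNull(n_iter=50, min_p=np.full(50, 0.01), seed=0)
        est = threshold_with_ci(null, n_boot=200, seed=1)
        assert est.ci_low == pytest.approx(2.0)
        assert est.ci_high == pytest.approx(2.0)
        assert est.neg_log10_p_sig == pytest.approx(2.0)

    def test_ci_narrows_with_more_iterations(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.r_[np.zeros(20), np.ones(20)]
        narrower = 0
        n_rep = 10
        for k in range(n_rep):
            small = threshold_with_ci(
                min_p_permutation(X, y, n_iter=200, seed=k), n_boot=200, seed=k
            )
            big = threshold_with_ci(
                min_p_permutation(X, y, n_iter=2000, seed=100 + k), n_boot=200,
                seed=100 + k,
            )
            narrower += (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)
        assert narrower >= 8

    def test_estimator_class_wires_everything(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.r_[np.zeros(15), np.ones(15)]
        est = PermutationThreshold(n_iter=300, n_boot=200, seed=6).fit(X, y)
        assert est.min_p_.size == 300
        assert est.ci_low_ <= est.neg_log10_p_sig_ <= est.ci_high_


def walk_oracle(scores_desc, member_mask, exponent=1.0):
    """Step-by-step running-sum oracle for the weighted KS statistic."""
    n = len(scores_desc)
    n_hit = member_mask.sum()
    denom_hit = np.sum(np.abs(scores_desc[member_mask]) ** exponent)
    running = 0.0
    best = 0.0
    for i in range(n):
        if member_mask[i]:
            running += np.abs(scores_desc[i]) ** exponent / denom_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    @staticmethod
    def make_assoc(betas, ids=None):
        ids = ids or [f"K{i:05d}" for i in range(len(betas))]
        frame = pd.DataFrame(
            {"beta": betas, "se": np.ones(len(betas)),
             "p_value": np.full(len(betas), 0.5)},
            index=pd.Index(ids, name="gene_id"),
        )
        return AssociationResult(table=frame, n_tested=len(betas))

    def test_size_filter_boundaries(self, rng):
        betas = rng.normal(size=200)
        assoc = self.make_assoc(betas)
        genes = list(assoc.feature_ids)
        sets = GeneSetCollection(sets={
            "tiny": genes[:49],           # 49 genes -> excluded
            "edge": genes[:50],           # 50 genes -> retained
            "big": genes[:120],
        })
        res = gsea_effect_ranked(assoc, sets, n_perm=20, seed=0,
                                 min_size=50, max_size=30000)
        assert "tiny" not in res.table.index
        assert {"edge", "big"} <= set(res.table.index)

    def test_running_sum_matches_walk_oracle_20_genes(self, rng):
        betas = rng.normal(size=20)
        order = np.argsort(-betas)
        sorted_betas = betas[order]
        mask = np.zeros(20, dtype=bool)
        mask[[0, 1, 2, 7, 15]] = True
        assert enrichment_score(sorted_betas, mask) == pytest.approx(
            walk_oracle(sorted_betas, mask), abs=1e-12
        )

    def test_top_ranked_set_attains_analytic_maximum(self):
        betas = np.linspace(3.0, -3.0, 20)
        mask = np.zeros(20, dtype=bool)
        mask[:5] = True  # exactly the top of the ranking
        es = enrichment_score(betas, mask)
        # walk peaks right after the last hit: sum of hit increments minus
        # zero misses... all hits come first, so the peak is exactly 1
        assert es == pytest.approx(1.0)

    def test_loaded_set_detected(self, rng):
        betas = np.r_[rng.normal(3, 0.2, size=10), rng.normal(0, 1, size=90)]
        assoc = self.make_assoc(betas)
        genes = list(assoc.feature_ids)
        loaded = genes[:10] + genes[50:70]
        random_set = genes[30:60]
        sets = GeneSetCollection(sets={"loaded": loaded, "rand": random_set})
        res = gsea_effect_ranked(assoc, sets, n_perm=500, seed=1,
                                 min_size=20, max_size=30000)
        assert res.table.loc["loaded", "es"] > 0
        assert res.table.loc["loaded", "p_value"] < 0.05

    def test_null_p_values_calibrated(self):
        """Random sets against a null ranking reject at ~5%."""
        g = np.random.default_rng(33)
        hits = 0
        n_rep = 200
        for k in range(n_rep):
            betas = g.normal(size=60)
            assoc = self.make_assoc(betas)
            genes = np.asarray(assoc.feature_ids)
            sets = GeneSetCollection(
                sets={"s": g.choice(genes, size=20, replace=False).tolist()}
            )
            res = gsea_effect_ranked(assoc, sets, n_perm=99,
                                     seed=int(g.integers(2**31)),
                                     min_size=10, max_size=30000)
            hits += res.table["p_value"].iloc[0] <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3 * se + 0.01

    def test_unresolvable_ids_dropped_and_counted(self, rng):
        assoc = self.make_assoc(rng.normal(size=30))
        genes = list(assoc.feature_ids)
        sets = GeneSetCollection(sets={"s": genes[:15] + ["missing_1", "missing_2"]})
        res = gsea_effect_ranked(assoc, sets, n_perm=20, seed=0,
                                 min_size=10, max_size=30000)
        assert res.dropped_gene_ids == 2
        assert res.table.loc["s", "set_size"] == 15

    def test_empty_retained_collection_raises(self, rng):
        assoc = self.make_assoc(rng.normal(size=30))
        sets = GeneSetCollection(sets={"s": list(assoc.feature_ids)[:5]})
        with pytest.raises(ValueError, match="size filter"):
            gsea_effect_ranked(assoc, sets, n_perm=10, seed=0,
                               min_size=50, max_size=30000)
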