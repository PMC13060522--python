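"""Module-scoring stage: imputation, PCA, MANOVA, hierarchical regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcoex.modules import (
    eta_squared_from_F,
    fit_pca,
    hierarchical_regression,
    impute_group_mean,
    manova_two_group,
    retain_components,
)


def _frame(arr, genes=None, cases=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cases = cases or [f"c{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cases)


class TestImpute:
    def test_missing_replaced_by_group_mean(self):
        m = _frame([[1.0, np.nan, 3.0, 5.0, np.nan, 7.0]])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=m.columns)
        out = impute_group_mean(m, groups)
        assert out.iloc[0].tolist() == [1.0, 2.0, 3.0, 5.0, 6.0, 7.0]

    def test_no_missing_is_identity(self, rng):
        m = _frame(rng.normal(size=(4, 6)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=m.columns)
        assert impute_group_mean(m, groups).equals(m)

    def test_group_means_preserved(self, rng):
        arr = rng.normal(size=(5, 8))
        arr[rng.random(arr.shape) < 0.2] = np.nan
        m = _frame(arr)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=m.columns)
        if m[m.columns[:4]].isna().all(axis=1).any() or m[m.columns[4:]].isna().all(axis=1).any():
            pytest.skip("degenerate draw")
        out = impute_group_mean(m, groups)
        for cols in (m.columns[:4], m.columns[4:]):
            assert np.allclose(out[cols].mean(axis=1), m[cols].mean(axis=1))

    def test_fully_missing_group_rejected_with_gene_named(self):
        m = _frame([[np.nan, np.nan, 1.0, 2.0]], genes=["badgene"])
        groups = pd.Series(["a", "a", "b", "b"], index=m.columns)
        with pytest.raises(ValueError, match="badgene"):
            impute_group_mean(m, groups)


class TestPCA:
    def test_two_perfectly_correlated_genes(self, rng):
        x = rng.normal(size=10)
        m = _frame([x, 2 * x + 1])
        model = fit_pca(m, n_retained=1)
        assert model.var_explained[0] == pytest.approx(1.0)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_eigenvalues_sum_to_gene_count(self, rng):
        m = _frame(rng.normal(size=(6, 12)))
        model = fit_pca(m, n_retained=2)
        assert model.eigenvalues.sum() == pytest.approx(6.0)

    def test_independent_genes_flat_spectrum_at_large_n(self, rng):
        m = _frame(rng.normal(size=(4, 4000)))
        model = fit_pca(m, n_retained=2)
        assert np.allclose(model.var_explained, 0.25, atol=0.04)

    def test_scores_uncorrelated_and_unit_variance(self, rng):
        m = _frame(rng.normal(size=(5, 30)))
        model = fit_pca(m, n_retained=3)
        S = model.scores.to_numpy()
        C = np.corrcoef(S.T)
        assert np.allclose(C - np.eye(3), 0.0, atol=1e-8)
        assert np.allclose(S.std(axis=0, ddof=1), 1.0)

    def test_rank_deficiency_flagged_when_genes_exceed_cases(self, rng):
        m = _frame(rng.normal(size=(20, 8)))
        model = fit_pca(m, n_retained=2)
        assert "rank_deficient" in model.flags
        assert model.communalities.between(0, 1 + 1e-9).all()

    def test_deterministic_sign_convention(self, rng):
        m = _frame(rng.normal(size=(5, 10)))
        l1 = fit_pca(m, n_retained=2).loadings
        l2 = fit_pca(m, n_retained=2).loadings
        assert np.allclose(l1, l2)
        top = l1["PC1"].abs().idxmax()
        assert l1.loc[top, "PC1"] > 0


class TestRetention:
    def test_scree_elbow_example(self):
        assert retain_components([5.8, 1.3, 0.4, 0.3, 0.2]) == 2

    def test_fixed_k(self):
        assert retain_components([3, 2, 1], rule="fixed-k", k=2) == 2
        with pytest.raises(ValueError):
            retain_components([3.0], rule="fixed-k", k=2)

    def test_degenerate_scree_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert retain_components([1.0, 1.0, 1.0, 1.0]) == 2

    def test_ascending_rejected(self):
        with pytest.raises(ValueError):
            retain_components([1.0, 2.0])


class TestManova:
    @staticmethod
    def _scores(rng, n_per=8, p=2, shift=0.0):
        a = rng.normal(size=(n_per, p))
        b = rng.normal(loc=shift, size=(n_per, p))
        scores = pd.DataFrame(
            np.vstack([a, b]), columns=[f"PC{i+1}" for i in range(p)],
            index=[f"s{i}" for i in range(2 * n_per)],
        )
        groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=scores.index)
        return scores, groups

    def test_one_component_reduces_to_anova_f(self, rng):
        scores, groups = self._scores(rng, p=1, shift=1.0)
        res = manova_two_group(scores, groups)
        f_anova = stats.f_oneway(
            scores.iloc[:8, 0], scores.iloc[8:, 0]
        ).statistic
        assert res.F == pytest.approx(f_anova)

    def test_matches_hotelling_t2_oracle(self, rng):
        scores, groups = self._scores(rng, p=2, shift=1.5)
        res = manova_two_group(scores, groups)
        # independent closed form: T^2 via pooled covariance
        a = scores.iloc[:8].to_numpy()
        b = scores.iloc[8:].to_numpy()
        n1 = n2 = 8
        S = ((n1 - 1) * np.cov(a.T) + (n2 - 1) * np.cov(b.T)) / (n1 + n2 - 2)
        diff = a.mean(0) - b.mean(0)
        t2 = (n1 * n2) / (n1 + n2) * diff @ np.linalg.solve(S, diff)
        n, p = n1 + n2, 2
        f_from_t2 = t2 * (n - p - 1) / (p * (n - 2))
        assert res.F == pytest.approx(f_from_t2)
        assert 0 < res.wilks_lambda <= 1

    def test_null_calibration(self):
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(s)
            scores, groups = self._scores(rng, shift=0.0)
            pvals.append(manova_two_group(scores, groups).p)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert frac == pytest.approx(0.05, abs=0.05)

    def test_requires_two_groups(self, rng):
        scores, groups = self._scores(rng)
        with pytest.raises(ValueError, match="two groups"):
            manova_two_group(scores, pd.Series("a", index=scores.index))


class TestEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(12.75, 1, 8, 0.614), (3.81, 1, 8, 0.322), (0.0, 1, 8, 0.0)],
    )
    def test_reported_values(self, F, df1, df2, expected):
        # the reported F values are rounded to 2 dp, so allow 1e-3
        assert eta_squared_from_F(F, df1, df2) == pytest.approx(expected, abs=1e-3)


class TestHierarchicalRegression:
    def test_single_predictor_identities(self, rng):
        """R^2 = F/(F+df2) and |beta| = sqrt(R^2) for any one-predictor fit."""
        y = rng.normal(size=9)
        group = ["control"] * 5 + ["case"] * 4
        res = hierarchical_regression(y, group)
        df2 = res.df_model1[1]
        assert res.r2_model1 == pytest.approx(
            res.f_model1 / (res.f_model1 + df2))
        assert abs(res.beta_group_m1) == pytest.approx(np.sqrt(res.r2_model1))

    @pytest.mark.parametrize(
        "F,df2,r2,beta",
        [(42.50, 6, 0.876, 0.936), (15.04, 7, 0.682, 0.826)],
    )
    def test_reported_model1_statistics_are_consistent(self, F, df2, r2, beta):
        assert eta_squared_from_F(F, 1, df2) == pytest.approx(r2, abs=5e-4)
        assert np.sqrt(eta_squared_from_F(F, 1, df2)) == pytest.approx(beta, abs=5e-4)

    def test_model2_monotone_and_fchange(self, rng):
        y = rng.normal(size=10)
        group = ["control"] * 5 + ["case"] * 5
        cov = ["yes", "no", "no", "yes", "no", "yes", "yes", "no", "unknown", "no"]
        res = hierarchical_regression(y, group, cov)
        assert res.r2_model2 >= res.r2_model1 - 1e-12
        expected_fc = res.delta_r2 / ((1 - res.r2_model2) / (res.n - 3))
        assert res.f_change == pytest.approx(expected_fc)

    def test_confounded_covariate_flagged(self, rng):
        y = rng.normal(size=8)
        group = ["control"] * 4 + ["case"] * 4
        cov = ["no"] * 4 + ["yes"] * 4
        res = hierarchical_regression(y, group, cov)
        assert "covariate_collinear_with_group" in res.flags
        assert res.delta_r2 == 0.0

    def test_listwise_unknown_policy_drops_cases(self, rng):
        y = rng.normal(size=10)
        group = ["control"] * 5 + ["case"] * 5
        cov = ["yes", "no", "unknown", "yes", "no"] * 2
        res = hierarchical_regression(y, group, cov, unknown_policy="listwise")
        assert res.n == 8
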