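"""Trial statistics: regression validation, correlations, PCA,
augmented-RCBD adjustment and heritability."""

import numpy as np
import pandas as pd
import pytest

from crownpheno import (DesignError, DomainError, augmented_rcbd_adjust,
                        broad_sense_heritability, correlation_matrix,
                        make_trial_dataset, normality_check, pca_traits,
                        validation_regression)


class TestValidationRegression:
    def test_perfect_estimates(self):
        res = validation_regression([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.r_squared == pytest.approx(1.0)
        assert res.mean_abs_pct_error == pytest.approx(0.0)

    def test_correlation_is_not_accuracy(self):
        res = validation_regression([1.0, 2, 3], [2.0, 4, 6])
        assert res.r_squared == pytest.approx(1.0)
        assert res.mean_abs_pct_error == pytest.approx(100.0)

    def test_four_point_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.1, 1.9, 3.2, 3.8])
        # independent closed-form OLS: b = Sxy/Sxx, a = ybar - b xbar
        sxx = ((t - t.mean()) ** 2).sum()
        sxy = ((t - t.mean()) * (e - e.mean())).sum()
        syy = ((e - e.mean()) ** 2).sum()
        res = validation_regression(t, e)
        assert res.slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert res.intercept == pytest.approx(e.mean()
                                              - sxy / sxx * t.mean(),
                                              rel=1e-9)
        assert res.r_squared == pytest.approx(sxy ** 2 / (sxx * syy),
                                              rel=1e-12)
        pct = np.abs(e - t) / t * 100
        assert res.mean_abs_pct_error == pytest.approx(pct.mean())
        assert res.max_abs_pct_error == pytest.approx(pct.max())

    def test_constant_truth_errors(self):
        with pytest.raises(DomainError):
            validation_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(19, 5)),
                             columns=list("abcde"))
        res = correlation_matrix(table)
        assert res.df.loc["a", "b"] == 17

    def test_exact_linear_relation(self):
        x = np.arange(1.0, 11.0)
        res = correlation_matrix(pd.DataFrame({"x": x, "y": 2 * x}))
        assert res.r_matrix.loc["x", "y"] == pytest.approx(1.0)
        assert res.p_matrix.loc["x", "y"] < 1e-10
        assert res.stars.loc["x", "y"] == "***"

    def test_four_point_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        r_direct = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        res = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        assert res.r_matrix.loc["x", "y"] == pytest.approx(r_direct,
                                                           rel=1e-12)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(12, 4)),
                             columns=list("abcd"))
        res = correlation_matrix(table)
        np.testing.assert_allclose(res.r_matrix, res.r_matrix.T)
        np.testing.assert_allclose(np.diag(res.r_matrix), 1.0)

    def test_constant_column_marked_missing(self):
        table = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        res = correlation_matrix(table)
        assert np.isnan(res.r_matrix.loc["x", "c"])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(15, 3)),
                             columns=list("abc"))
        scaled = table * [3.0, 0.1, 7.0] + [5.0, -2.0, 0.0]
        r0 = correlation_matrix(table).r_matrix
        r1 = correlation_matrix(scaled).r_matrix
        np.testing.assert_allclose(r0, r1, atol=1e-12)


class TestPca:
    def test_eigenvalue_sum_is_variable_count(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(40, 7)))
        res = pca_traits(table)
        assert res.eigenvalues.sum() == pytest.approx(7.0, rel=1e-9)
        assert res.cumulative_pct[-1] == pytest.approx(100.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_two_variable_analytic_eigenvalues(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 0.6 * x + 0.8 * rng.normal(size=300)
        table = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        res = pca_traits(table)
        assert res.eigenvalues[0] == pytest.approx(1 + abs(r), abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(1 - abs(r), abs=1e-9)

    def test_uncorrelated_eigenvalues_near_one(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(10000, 5)))
        res = pca_traits(table)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.1)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        table = pd.DataFrame(X)
        res = pca_traits(table)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = PCA().fit(Z)
        # covariance of ddof-1-standardized data is the correlation
        # matrix, so the spectra must agree
        np.testing.assert_allclose(res.eigenvalues,
                                   sk.explained_variance_, rtol=1e-6)

    def test_missing_values_rejected(self):
        table = pd.DataFrame({"x": [1.0, np.nan, 3.0, 4.0],
                              "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(DomainError):
            pca_traits(table)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(30, 3)))
        res = pca_traits(table)
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0


TOY = pd.DataFrame([
    # checks in both blocks; block 2 runs 5 higher than block 1
    ("c1", "b1", True, 10.0), ("c2", "b1", True, 12.0),
    ("c1", "b2", True, 15.0), ("c2", "b2", True, 17.0),
    ("t1", "b2", False, 20.0), ("t2", "b1", False, 8.0),
], columns=["genotype", "block", "is_check", "y"])


class TestAugmentedRcbd:
    def test_hand_worked_toy(self):
        """Checks: block means 11 and 16, grand mean 13.5, so block
        effects are -2.5 and +2.5; t1 (block 2) adjusts 20 -> 17.5 and
        t2 (block 1) adjusts 8 -> 10.5."""
        adj = augmented_rcbd_adjust(TOY, "y")
        assert adj.block_effects["b1"] == pytest.approx(-2.5)
        assert adj.block_effects["b2"] == pytest.approx(2.5)
        assert adj.means["t1"] == pytest.approx(17.5)
        assert adj.means["t2"] == pytest.approx(10.5)
        assert adj.means["c1"] == pytest.approx(12.5)

    def test_zero_block_effects_identity(self):
        df = make_trial_dataset(8, 3, 4, {"sigma2_G": 2.0,
                                          "sigma2_block": 0.0,
                                          "sigma2_e": 0.0},
                                {"v": 10.0}, seed=2)
        adj = augmented_rcbd_adjust(df, "v")
        raw = df[~df["is_check"]].set_index("genotype")["v"]
        for g, val in raw.items():
            assert adj.means[g] == pytest.approx(val, abs=1e-9)

    def test_missing_check_is_design_error(self):
        broken = TOY.drop(index=2)  # c1 absent from block b2
        with pytest.raises(DesignError, match="c1"):
            augmented_rcbd_adjust(broken, "y")

    def test_anova_check_decomposition_adds_up(self):
        df = make_trial_dataset(10, 4, 5, {"sigma2_G": 2.0,
                                           "sigma2_block": 1.0,
                                           "sigma2_e": 1.5},
                                {"v": 50.0}, seed=3)
        adj = augmented_rcbd_adjust(df, "v")
        an = adj.anova.set_index("source")
        checks = df[df["is_check"]]
        total_ss = float(((checks["v"] - checks["v"].mean()) ** 2).sum())
        parts = (an.loc["blocks (from checks)", "sum_sq"]
                 + an.loc["checks", "sum_sq"]
                 + an.loc["error (check replication)", "sum_sq"])
        assert parts == pytest.approx(total_ss, rel=1e-9)


class TestHeritability:
    def test_definitional_injection(self):
        df = make_trial_dataset(60, 5, 9, {"sigma2_G": 3.0,
                                           "sigma2_block": 1.0,
                                           "sigma2_e": 1.0},
                                {"v": 100.0}, seed=4)
        h = broad_sense_heritability(df, "v")
        assert h.H2 == pytest.approx(0.75, abs=0.15)

    def test_zero_genetic_variance_floors_at_zero(self):
        df = make_trial_dataset(30, 5, 9, {"sigma2_G": 0.0,
                                           "sigma2_block": 1.0,
                                           "sigma2_e": 2.0},
                                {"v": 10.0}, seed=5)
        h = broad_sense_heritability(df, "v")
        assert 0.0 <= h.H2 <= 0.25

    def test_too_few_tests_errors(self):
        df = make_trial_dataset(2, 2, 2, {"sigma2_G": 1.0,
                                          "sigma2_block": 0.0,
                                          "sigma2_e": 1.0},
                                {"v": 0.0}, seed=6)
        one = df[df["is_check"] | (df["genotype"] == "test_1")]
        with pytest.raises(DesignError):
            broad_sense_heritability(one, "v")


class TestNormality:
    def test_normal_sample_high_w(self):
        rng = np.random.default_rng(9)
        res = normality_check(rng.normal(size=1000))
        assert res["shapiro_w"] > 0.99
        assert len(res["sample_quantiles"]) == 1000

    def test_exponential_lower_w_than_normal(self):
        rng = np.random.default_rng(9)
        w_norm = normality_check(rng.normal(size=500))["shapiro_w"]
        rng = np.random.default_rng(9)
        w_exp = normality_check(rng.exponential(size=500))["shapiro_w"]
        assert w_exp < w_norm

    def test_constant_errors(self):
        with pytest.raises(DomainError):
            normality_check([1.0, 1.0, 1.0, 1.0])
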