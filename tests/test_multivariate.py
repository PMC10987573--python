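import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catchstat import (auto_select_method, correlation_test, fit_lasso,
                       fit_logistic, fit_ols, format_regression_table,
                       get_fitter, lasso_lambda_max, percent_contributions,
                       rank_factors, standardize)
from catchstat.multivariate import RegressionResult

from conftest import make_table

# printed report coefficients from the two published worked examples
TABLE3_COEFS = {"Poverty_rate": 0.112, "Neighborhood_safety_rate": -0.450,
                "Demographics_Females": 0.257}
TABLE4_COEFS = {"Poverty_rate": 0.432, "Teen_birth_rate": 0.398,
                "Uninsured_rate": -0.238,
                "Demographics_Hispanic_or_Latino": -0.175,
                "Routine_checkup_rate": -0.023,
                "Single_parent_households": 0.031,
                "Demographics_Males": -0.007}


def named_frame(X, names=None):
    names = names or [f"x{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestStandardize:
    def test_exact_moments(self):
        table = make_table({"v": [1.0, 2.0, 3.0]})
        std, scaling = standardize(table, ["v"])
        out = std.data["v"].to_numpy()
        assert out.mean() == pytest.approx(0.0, abs=1e-15)
        assert out.std(ddof=1) == pytest.approx(1.0)
        assert scaling["v"] == (2.0, 1.0)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        table = make_table({"v": rng.normal(5, 3, 40)})
        once, _ = standardize(table, ["v"])
        twice, _ = standardize(once, ["v"])
        assert np.allclose(once.data["v"], twice.data["v"], atol=1e-12)

    def test_zero_sd_error(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            standardize(make_table({"v": [2.0, 2.0, 2.0]}), ["v"])


class TestFitOls:
    def test_exact_fit(self):
        x = np.arange(10.0)
        res = fit_ols(x, x[:, None])
        assert res.coefficients["x1"] == pytest.approx(1.0)
        assert res.r2_adjusted == pytest.approx(1.0)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(50)
        X = rng.standard_normal((50, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(50)
        res = fit_ols(y, X)
        Xd = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate(res.features):
            assert res.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-8)
        # adjusted R^2 from its definition
        resid = y - Xd @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        r2_adj = 1 - (1 - r2) * (50 - 1) / (50 - 3 - 1)
        assert res.r2_adjusted == pytest.approx(r2_adj, abs=1e-10)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(77)
        n, beta = 500, np.array([0.5, -0.3, 0.2])
        X = rng.standard_normal((n, 3))
        y = X @ beta + rng.standard_normal(n)
        res = fit_ols(y, X)
        for j, name in enumerate(res.features):
            err = abs(res.coefficients[name] - beta[j])
            assert err <= 3 * res.standard_errors[name]

    def test_ci_coverage(self):
        """Nominal 95% CI coverage over 200 simulated fits in [90%, 99%]."""
        beta = np.array([0.5, -0.3, 0.2])
        n = 100
        hits = total = 0
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            X = rng.standard_normal((n, 3))
            y = X @ beta + rng.standard_normal(n)
            res = fit_ols(y, X)
            tcrit = stats.t.ppf(0.975, n - 3 - 1)
            for j, name in enumerate(res.features):
                half = tcrit * res.standard_errors[name]
                hits += abs(res.coefficients[name] - beta[j]) <= half
                total += 1
        assert 0.90 <= hits / total <= 0.99

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        y = X @ [1.0, 0.5, -0.2] + rng.standard_normal(60)
        a = fit_ols(y, named_frame(X, ["a", "b", "c"]))
        b = fit_ols(y, named_frame(X[:, ::-1], ["c", "b", "a"]))
        for name in ("a", "b", "c"):
            assert a.coefficients[name] == pytest.approx(
                b.coefficients[name], abs=1e-10)
            assert a.percent_contribution[name] == pytest.approx(
                b.percent_contribution[name], abs=1e-9)
        assert a.r2_adjusted == pytest.approx(b.r2_adjusted, abs=1e-12)

    def test_single_standardized_feature_beta_is_pearson_r(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(80)
        y = 0.6 * x + rng.standard_normal(80)
        table = make_table({"y": y, "x": x})
        std, _ = standardize(table, ["y", "x"])
        res = fit_ols(std.data["y"], std.data[["x"]])
        r = correlation_test(x, y).r
        assert res.coefficients["x"] == pytest.approx(r, abs=1e-12)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        X = named_frame(np.column_stack([x, 2 * x]), ["a", "a_scaled"])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(rng.standard_normal(30), X)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="n > p"):
            fit_ols(np.arange(3.0), np.eye(3))


class TestFitLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        n = 2000
        X = rng.standard_normal((n, 2))
        eta = X @ [1.0, -1.0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_logistic(y, X)
        for name, true in zip(res.features, (1.0, -1.0)):
            assert abs(res.coefficients[name] - true) <= \
                3 * res.standard_errors[name]

    def test_null_feature_type_one_error(self):
        """A zero-effect feature is rejected at 5% in <= 10/100 seeds."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            X = rng.standard_normal((n, 2))
            eta = X[:, 0]  # second feature has no effect
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            res = fit_logistic(y, X)
            if res.p_values["x2"] < 0.05:
                rejections += 1
        assert rejections <= 10

    def test_single_class_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(50), rng.standard_normal((50, 2)))

    def test_non_binary_outcome_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic(rng.standard_normal(50), rng.standard_normal((50, 2)))

    def test_perfect_separation_error(self):
        x = np.concatenate([-np.arange(1.0, 26.0), np.arange(1.0, 26.0)])
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(y, x[:, None])


class TestFitLasso:
    @staticmethod
    def standardized_problem(seed=0, n=40, p=3, beta=None):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        beta = np.asarray(beta if beta is not None else [1.0, -0.5, 0.0][:p])
        y = X @ beta + 0.5 * rng.standard_normal(n)
        return y, X

    def test_lambda_zero_equals_ols(self):
        y, X = self.standardized_problem()
        lasso = fit_lasso(y, X, lam=0.0)
        ols = fit_ols(y, X)
        for name in lasso.features:
            assert lasso.coefficients[name] == pytest.approx(
                ols.coefficients[name], abs=1e-6)

    def test_lambda_max_zeroes_everything(self):
        y, X = self.standardized_problem(seed=3)
        lam_max = lasso_lambda_max(y - y.mean(), X)
        res = fit_lasso(y, X, lam=lam_max)
        assert all(b == 0.0 for b in res.coefficients.values())
        assert all(v == 0.0 for v in res.percent_contribution.values())

    def test_kkt_conditions(self):
        """Independent optimality verifier for the coordinate-descent fit."""
        y, X = self.standardized_problem(seed=7, n=40, p=2, beta=[0.8, -0.1])
        lam = 0.1
        res = fit_lasso(y, X, lam=lam)
        beta = np.array([res.coefficients[f] for f in res.features])
        resid = (y - y.mean()) - X @ beta
        grad = X.T @ resid / len(y)
        for j, b in enumerate(beta):
            if b != 0:
                assert grad[j] == pytest.approx(lam * np.sign(b), abs=1e-6)
            else:
                assert abs(grad[j]) <= lam + 1e-8

    def test_sklearn_cross_check(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        y, X = self.standardized_problem(seed=11, n=80, p=4,
                                         beta=[1.0, -0.5, 0.3, 0.0])
        lam = 0.05
        ours = fit_lasso(y, X, lam=lam)
        ref = sklearn_linear.Lasso(alpha=lam, fit_intercept=True,
                                   tol=1e-10).fit(X, y)
        for j, name in enumerate(ours.features):
            assert ours.coefficients[name] == pytest.approx(
                ref.coef_[j], abs=1e-5)

    def test_soft_threshold_closed_form_orthonormal(self):
        """On X with X'X/n = I the path is coordinatewise soft-thresholding,
        monotone in lambda."""
        rng = np.random.default_rng(9)
        n, p = 64, 2
        M = rng.standard_normal((n, p))
        Q, _ = np.linalg.qr(M - M.mean(0))
        X = Q * np.sqrt(n)  # columns orthonormal after /sqrt(n)
        y = X @ [1.0, -0.6] + 0.1 * rng.standard_normal(n)
        yc = y - y.mean()
        z = X.T @ yc / n
        prev = None
        for lam in (0.0, 0.1, 0.3, 0.5, 0.8):
            res = fit_lasso(y, X, lam=lam)
            beta = np.array([res.coefficients[f] for f in res.features])
            expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
            assert np.allclose(beta, expected, atol=1e-6)
            if prev is not None:
                assert (np.abs(beta) <= np.abs(prev) + 1e-9).all()
            prev = beta

    def test_cv_lambda_deterministic_and_sane(self):
        y, X = self.standardized_problem(seed=13, n=60, p=3)
        a = fit_lasso(y, X, seed=42)
        b = fit_lasso(y, X, seed=42)
        assert a.lam == b.lam
        assert 0 < a.lam < lasso_lambda_max(y - y.mean(), X)
        assert a.p_values is None and a.t_values is None

    def test_negative_lambda_rejected(self):
        y, X = self.standardized_problem()
        with pytest.raises(ValueError, match="non-negative"):
            fit_lasso(y, X, lam=-0.1)


class TestPercentContributions:
    def test_published_seven_feature_example(self):
        contrib = percent_contributions(TABLE4_COEFS)
        assert contrib["Teen_birth_rate"] == pytest.approx(30.5, abs=0.05)
        assert contrib["Poverty_rate"] == pytest.approx(33.1, abs=0.05)
        assert contrib["Uninsured_rate"] == pytest.approx(18.3, abs=0.05)
        assert contrib["Demographics_Hispanic_or_Latino"] == pytest.approx(
            13.4, abs=0.05)
        assert contrib["Single_parent_households"] == pytest.approx(2.4,
                                                                    abs=0.05)

    def test_published_three_feature_example(self):
        contrib = percent_contributions(TABLE3_COEFS)
        assert contrib["Demographics_Females"] == pytest.approx(31.4, abs=0.05)
        # the other two printed cells carry more-digit internal coefficients
        # (printed 13.6 / 55.0 vs 13.7 / 54.9 from the 3-decimal inputs)
        assert contrib["Poverty_rate"] == pytest.approx(13.675, abs=0.001)

    def test_single_coefficient_is_100(self):
        assert percent_contributions({"only": -0.3}) == {"only": 100.0}

    def test_sums_to_100(self):
        rng = np.random.default_rng(4)
        coefs = {f"f{i}": float(v) for i, v in
                 enumerate(rng.standard_normal(9))}
        assert sum(percent_contributions(coefs).values()) == pytest.approx(
            100.0, abs=1e-9)

    def test_all_zero_error(self):
        with pytest.raises(ValueError, match="all coefficients are zero"):
            percent_contributions({"a": 0.0, "b": 0.0})


class TestAutoSelectAndRanking:
    def test_binary_outcome_selects_logistic(self):
        rng = np.random.default_rng(0)
        table = make_table({"y": (rng.random(40) < 0.5).astype(float),
                            "a": rng.standard_normal(40),
                            "b": rng.standard_normal(40)})
        assert auto_select_method(table, "y", ["a", "b"]) == "logistic"

    def test_wide_problem_selects_lasso(self):
        rng = np.random.default_rng(1)
        cols = {"y": rng.standard_normal(40)}
        cols.update({f"s{i}": rng.standard_normal(40) for i in range(30)})
        table = make_table(cols)
        assert auto_select_method(table, "y", list(cols)[1:]) == "lasso"

    def test_collinear_secondaries_select_lasso(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(100)
        table = make_table({"y": rng.standard_normal(100), "a": a,
                            "b": a + 0.01 * rng.standard_normal(100),
                            "c": rng.standard_normal(100)})
        assert auto_select_method(table, "y", ["a", "b", "c"]) == "lasso"

    def test_default_is_ols(self):
        rng = np.random.default_rng(3)
        table = make_table({"y": rng.standard_normal(77),
                            "a": rng.standard_normal(77),
                            "b": rng.standard_normal(77),
                            "c": rng.standard_normal(77)})
        assert auto_select_method(table, "y", ["a", "b", "c"]) == "ols"

    def test_rank_published_order(self):
        result = RegressionResult(
            model_kind="ols", features=list(TABLE4_COEFS),
            coefficients=TABLE4_COEFS,
            percent_contribution=percent_contributions(TABLE4_COEFS),
            intercept=0.0, n=77)
        ranking = rank_factors(result)
        assert ranking.top(3) == ["Poverty_rate", "Teen_birth_rate",
                                  "Uninsured_rate"]

    def test_rank_single_dominant(self):
        coefs = {"a": 0.0, "b": 0.7, "c": 0.0}
        result = RegressionResult(
            model_kind="ols", features=list(coefs), coefficients=coefs,
            percent_contribution=percent_contributions(coefs),
            intercept=0.0, n=10)
        ranking = rank_factors(result)
        assert ranking.features[0] == "b"
        assert ranking.contributions[0] == 100.0

    def test_rank_ties_keep_input_order(self):
        coefs = {"first": 0.5, "second": -0.5}
        result = RegressionResult(
            model_kind="ols", features=["first", "second"],
            coefficients=coefs,
            percent_contribution=percent_contributions(coefs),
            intercept=0.0, n=10)
        assert rank_factors(result).features == ["first", "second"]

    def test_registry_unimplemented_and_unknown(self):
        with pytest.raises(NotImplementedError, match="gbm"):
            get_fitter("gbm")
        with pytest.raises(NotImplementedError, match="neural_network"):
            get_fitter("neural_network")
        with pytest.raises(ValueError, match="unknown model kind"):
            get_fitter("random_forest")

    def test_formatted_table_layout(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 2))
        y = X @ [1.0, -0.5] + rng.standard_normal(50)
        text = format_regression_table(fit_ols(y, named_frame(X, ["a", "b"])))
        assert "Coeff (%) contribution" in text
        assert text.splitlines()[1].startswith("a")  # largest contribution first
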