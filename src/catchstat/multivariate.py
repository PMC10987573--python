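"""Multivariate models with percent-contribution feature importance.

All variables are standardized (mean 0, sd 1) before fitting so
coefficients are unit-comparable; a feature's importance is its *percent
contribution*

    contribution_k = 100 * |beta_k| / sum_j |beta_j|

over the non-intercept standardized coefficients, and features are ranked
by it in descending order.

Three model families are implemented:

* ``ols`` — least squares with t / two-sided p on n - p - 1 dof and
  adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) (via statsmodels).
* ``logistic`` — maximum likelihood by iteratively reweighted least
  squares with Wald z / p (via statsmodels).
* ``lasso`` — coordinate descent on (1/(2n))||y - Xb||^2 + lambda*||b||_1;
  the default lambda is chosen by seeded 5-fold cross-validation over a
  log-spaced grid.  No p values are reported: naive inference is invalid
  after L1 selection.

``auto_select_method`` picks among them from the data shape: a binary
outcome gets logistic; many features (p >= n/2) or strongly collinear
features (any pairwise |r| > 0.9) get lasso; otherwise OLS.  Gradient
boosting and neural networks are registry entries that raise
NotImplementedError: the family is named but unparameterized here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import CommunityTable

logger = logging.getLogger(__name__)

MODEL_KINDS = ("ols", "logistic", "lasso")

#: families named in the interface but intentionally unimplemented
UNIMPLEMENTED_KINDS = ("gbm", "neural_network")


@dataclass
class RegressionResult:
    """Fitted multivariate model in the standard report layout."""

    model_kind: str
    features: list[str]
    coefficients: dict[str, float]
    percent_contribution: dict[str, float]
    intercept: float
    n: int
    t_values: dict[str, float] | None = None
    p_values: dict[str, float] | None = None
    r2_adjusted: float | None = None
    lam: float | None = None
    standard_errors: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class ImportanceRanking:
    """Features ordered by descending percent contribution; ties keep
    input order."""

    features: list[str]
    contributions: list[float]

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def standardize(
    table: CommunityTable, variables: list[str]
) -> tuple[CommunityTable, dict[str, tuple[float, float]]]:
    """Center the named variables to mean 0 and scale to sd 1 (ddof=1).

    Returns the rescaled table and the (mean, sd) pairs used, for
    reporting back on the original scale.
    """
    out = table.data.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for var in variables:
        col = out[var].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        mu = float(finite.mean())
        sd = float(finite.std(ddof=1))
        if sd == 0:
            raise ValueError(f"variable {var!r} has zero standard deviation")
        out[var] = (col - mu) / sd
        scaling[var] = (mu, sd)
    return CommunityTable(out), scaling


def percent_contributions(coefficients: dict[str, float]) -> dict[str, float]:
    """100 * |beta_k| / sum|beta_j| per feature (intercept excluded).

    Requires at least one nonzero coefficient; contributions sum to 100
    exactly before rounding.
    """
    total = sum(abs(b) for b in coefficients.values())
    if total == 0:
        raise ValueError("all coefficients are zero; contributions undefined")
    return {k: 100.0 * abs(b) / total for k, b in coefficients.items()}


def _design(y, X) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{j + 1}" for j in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(yv) & np.isfinite(Xm).all(axis=1)
    return yv[ok], Xm[ok], names


def _check_rank(Xd: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        from scipy.linalg import qr
        _, r, piv = qr(Xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        bad = [(["(intercept)"] + names)[j] for j in sorted(piv[rank:])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_ols(y, X) -> RegressionResult:
    """Least-squares fit with t / p per feature and adjusted R^2."""
    yv, Xm, names = _design(y, X)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    Xd = sm.add_constant(Xm, has_constant="add")
    _check_rank(Xd, names)
    fit = sm.OLS(yv, Xd).fit()
    coefs = dict(zip(names, fit.params[1:]))
    return RegressionResult(
        model_kind="ols", features=names, coefficients=coefs,
        percent_contribution=percent_contributions(coefs),
        intercept=float(fit.params[0]), n=n,
        t_values=dict(zip(names, fit.tvalues[1:])),
        p_values=dict(zip(names, fit.pvalues[1:])),
        standard_errors=dict(zip(names, fit.bse[1:])),
        r2_adjusted=float(fit.rsquared_adj))


def fit_logistic(y, X, *, max_iter: int = 100, tol: float = 1e-8
                 ) -> RegressionResult:
    """Logistic regression by IRLS with Wald z and two-sided p values.

    Raises on a single-class outcome or (quasi-)perfect separation, where
    the ML estimate diverges.
    """
    yv, Xm, names = _design(y, X)
    uniq = np.unique(yv)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if len(uniq) < 2:
        raise ValueError("outcome has a single class; both classes required")
    Xd = sm.add_constant(Xm, has_constant="add")
    _check_rank(Xd, names)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation/convergence are re-raised as errors below
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, Xd).fit(method="newton", maxiter=max_iter,
                                       tol=tol, disp=False)
    except Exception as exc:  # statsmodels PerfectSeparation / LinAlg errors
        raise ValueError(
            "logistic fit failed (likely perfect separation); "
            "consider lasso regularization") from exc
    converged = bool(fit.mle_retvals.get("converged", True))
    if (not converged or not np.isfinite(fit.params).all()
            or np.abs(fit.params).max() > 1e4):
        raise ValueError(
            "diverging coefficients indicate perfect separation; "
            "consider lasso regularization")
    coefs = dict(zip(names, fit.params[1:]))
    return RegressionResult(
        model_kind="logistic", features=names, coefficients=coefs,
        percent_contribution=percent_contributions(coefs),
        intercept=float(fit.params[0]), n=len(yv),
        t_values=dict(zip(names, fit.tvalues[1:])),
        p_values=dict(zip(names, fit.pvalues[1:])),
        standard_errors=dict(zip(names, fit.bse[1:])))


# ---------------------------------------------------------------------------
# lasso: coordinate descent on (1/(2n))||y - Xb||^2 + lam * ||b||_1
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _coordinate_descent(y: np.ndarray, X: np.ndarray, lam: float,
                        tol: float = 1e-7, max_iter: int = 10_000
                        ) -> np.ndarray:
    n, p = X.shape
    beta = np.zeros(p)
    col_sq = (X ** 2).sum(axis=0) / n
    resid = y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = X[:, j] @ resid / n + col_sq[j] * beta[j]
            new = _soft_threshold(rho, lam) / col_sq[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= delta * X[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


def lasso_lambda_max(y: np.ndarray, X: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero:
    max_j |X_j^T y| / n."""
    n = len(y)
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


def _cv_lambda(y: np.ndarray, X: np.ndarray, seed: int, n_folds: int = 5,
               n_grid: int = 50) -> float:
    """5-fold CV over a log grid from lambda_max down to lambda_max/1000."""
    rng = np.random.default_rng(seed)
    n = len(y)
    lam_max = lasso_lambda_max(y, X)
    if lam_max == 0:
        return 0.0
    grid = np.geomspace(lam_max, lam_max / 1000.0, n_grid)
    folds = rng.permutation(n) % n_folds
    errors = np.zeros(n_grid)
    for f in range(n_folds):
        test = folds == f
        ytr, Xtr = y[~test], X[~test]
        yte, Xte = y[test], X[test]
        mu = ytr.mean()
        for i, lam in enumerate(grid):
            beta = _coordinate_descent(ytr - mu, Xtr, lam)
            pred = mu + Xte @ beta
            errors[i] += ((yte - pred) ** 2).sum()
    return float(grid[int(np.argmin(errors))])


def fit_lasso(y, X, lam: float | None = None, *, seed: int = 0
              ) -> RegressionResult:
    """L1-penalized least squares by coordinate descent.

    Expects standardized features and reports coefficients on that scale;
    y is centered internally.  ``lam=None`` selects the penalty by seeded
    5-fold cross-validation.  At ``lam=0`` the solution coincides with
    OLS; at ``lam >= lambda_max`` every coefficient is exactly zero.
    No t or p values are attached.
    """
    yv, Xm, names = _design(y, X)
    if lam is not None and lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam is None:
        lam = _cv_lambda(yv, Xm, seed)
        logger.info("lasso lambda selected by 5-fold CV: %.6g", lam)
    mu = yv.mean()
    yc = yv - mu
    if lam > 0 and lam >= lasso_lambda_max(yc, Xm):
        # at or beyond lambda_max the all-zero solution is exact
        beta = np.zeros(Xm.shape[1])
    else:
        beta = _coordinate_descent(yc, Xm, lam)
    coefs = dict(zip(names, beta))
    if all(b == 0 for b in beta):
        contrib = {k: 0.0 for k in names}
    else:
        contrib = percent_contributions(coefs)
    return RegressionResult(
        model_kind="lasso", features=names, coefficients=coefs,
        percent_contribution=contrib, intercept=float(mu), n=len(yv),
        lam=float(lam))


_FITTERS = {"ols": fit_ols, "logistic": fit_logistic, "lasso": fit_lasso}


def get_fitter(kind: str):
    """Model registry lookup; named-but-unimplemented families raise."""
    if kind in _FITTERS:
        return _FITTERS[kind]
    if kind in UNIMPLEMENTED_KINDS:
        raise NotImplementedError(
            f"model family {kind!r} is part of the interface but not "
            "implemented: no standard parameterization is defined for it here")
    raise ValueError(f"unknown model kind {kind!r}")


def auto_select_method(table: CommunityTable, primary: str,
                       secondaries: list[str]) -> str:
    """Pick the model family from the data shape.

    Binary primary (<= 2 distinct non-missing values) -> logistic;
    p >= n/2 or any pairwise secondary |r| > 0.9 -> lasso; otherwise ols.
    """
    df = table.data[[primary] + list(secondaries)].dropna()
    n = len(df)
    p = len(secondaries)
    y = df[primary].to_numpy(dtype=float)
    if len(np.unique(y)) <= 2:
        logger.info("auto-select: binary outcome -> logistic")
        return "logistic"
    if p >= n / 2:
        logger.info("auto-select: p=%d >= n/2 (n=%d) -> lasso", p, n)
        return "lasso"
    if p >= 2:
        corr = np.abs(np.corrcoef(df[list(secondaries)].to_numpy(dtype=float),
                                  rowvar=False))
        np.fill_diagonal(corr, 0.0)
        if corr.max() > 0.9:
            logger.info("auto-select: collinear secondaries (max |r|=%.3f) "
                        "-> lasso", corr.max())
            return "lasso"
    logger.info("auto-select: continuous outcome, p=%d, n=%d -> ols", p, n)
    return "ols"


def rank_factors(result: RegressionResult) -> ImportanceRanking:
    """Features by descending percent contribution; stable ties."""
    order = sorted(range(len(result.features)),
                   key=lambda i: -result.percent_contribution[result.features[i]])
    feats = [result.features[i] for i in order]
    return ImportanceRanking(
        features=feats,
        contributions=[result.percent_contribution[f] for f in feats])


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10 ** ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def format_regression_table(result: RegressionResult) -> str:
    """Render a fitted model in the standard report layout
    (Feature | Coefficients | Coeff (%) contribution | t.value | P.value |
    R^2 adjusted), one decimal for contributions, rounded half away from
    zero."""
    header = ("Feature", "Coefficients", "Coeff (%) contribution",
              "t.value", "P.value", "R2 adjusted")
    rows = [header]
    for f in rank_factors(result).features:
        t = (f"{result.t_values[f]:.3f}" if result.t_values else "-")
        p = (f"{result.p_values[f]:.3f}" if result.p_values else "-")
        r2 = (f"{result.r2_adjusted:.3f}" if result.r2_adjusted is not None
              else "-")
        rows.append((f, f"{result.coefficients[f]:.3f}",
                     f"{_round_half_away(result.percent_contribution[f]):.1f}",
                     t, p, r2))
    widths = [max(len(r[i]) for r in rows) for i in range(6)]
    return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths))
                     for r in rows)
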