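"""Normality-transform selection.

Skewed community-level rates violate the normality assumptions behind
Pearson correlation and OLS inference.  This module applies a family of
candidate monotone transforms (identity, log, Box-Cox, Yeo-Johnson,
ordered-quantile normal scores) and keeps whichever minimizes the Pearson
chi-square goodness-of-fit statistic divided by its degrees of freedom —
the smaller the ratio, the closer the transformed sample is to Gaussian.

The Pearson statistic uses k = ceil(2 * n**0.4) equal-probability classes
under a Normal(mean, sd) fitted to the data, with dof = k - 3 (k - 1 minus
the two estimated parameters).  Box-Cox / Yeo-Johnson lambdas are fitted by
profile maximum likelihood on the grid [-5, 5] in steps of 0.01 —
deterministic and exhaustive at the sample sizes involved.

Transforms that do not apply to the data at hand (log / Box-Cox on
non-positive values) yield a sentinel report with ratio = +inf rather than
an exception, so the selection loop can always run to completion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: candidate order = tie-break precedence (prefer the simpler transform)
TRANSFORM_NAMES = ("identity", "log", "box_cox", "yeo_johnson", "ordered_quantile")

_LAMBDA_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 2)


class DegenerateVariableError(ValueError):
    """Raised when a variable has zero variance."""


@dataclass
class TransformReport:
    """A fitted candidate transform and its normality score."""

    transform_name: str
    parameters: dict[str, float] = field(default_factory=dict)
    p_statistic: float = math.inf
    dof: int = 0
    ratio: float = math.inf
    transformed_values: np.ndarray | None = None

    @property
    def applicable(self) -> bool:
        return self.transformed_values is not None

    def to_dict(self) -> dict:
        return {
            "transform_name": self.transform_name,
            "parameters": self.parameters,
            "p_statistic": self.p_statistic,
            "dof": self.dof,
            "ratio": self.ratio,
        }


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def pearson_normality_ratio(values) -> tuple[float, int, float]:
    """Pearson chi-square normality statistic, its dof, and their ratio.

    The sample is binned into k = ceil(2 * n**0.4) classes of equal
    probability under Normal(mean, sd) fitted to the data;
    P = sum((O_i - n/k)^2 / (n/k)) and dof = k - 3.

    Raises
    ------
    DegenerateVariableError
        If the (non-missing) sample has zero variance.
    ValueError
        If fewer than 10 non-missing values remain.
    """
    v = _clean(values)
    n = len(v)
    if n < 10:
        raise ValueError(f"need at least 10 non-missing values, got {n}")
    mu = v.mean()
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateVariableError("degenerate variable: zero variance")
    k = math.ceil(2 * n ** 0.4)
    # interior class boundaries at equal normal probability
    edges = stats.norm.ppf(np.arange(1, k) / k, loc=mu, scale=sd)
    observed = np.histogram(v, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = n / k
    p_stat = float(((observed - expected) ** 2 / expected).sum())
    dof = k - 3
    return p_stat, dof, p_stat / dof


def ordered_quantile_scores(values) -> np.ndarray:
    """Map ranks to normal scores: rank i of n -> Phi^-1((i - 0.5) / n).

    Ties share the average rank.  Depends only on the ordering of the
    input, never on its magnitudes.
    """
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(v))


def _boxcox_grid_llf(v: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood on the lambda grid, vectorized.

    llf(lam) = (lam - 1) * sum(log v) - n/2 * log(var_mle(y_lam)) with
    y_lam = (v**lam - 1)/lam (lam != 0) or log v (lam = 0).
    """
    n = len(v)
    logv = np.log(v)
    sum_logv = logv.sum()
    lam = _LAMBDA_GRID[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(lam == 0.0, logv[None, :],
                     np.expm1(lam * logv[None, :]) / np.where(lam == 0.0, 1.0, lam))
        var = y.var(axis=1)
        llf = (_LAMBDA_GRID - 1.0) * sum_logv - n / 2.0 * np.log(var)
    llf[~np.isfinite(llf)] = -np.inf
    return llf


def _yeojohnson_grid_llf(v: np.ndarray) -> np.ndarray:
    """Yeo-Johnson profile log-likelihood on the lambda grid, vectorized.

    llf(lam) = -n/2 * log(var_mle(psi(v, lam)))
               + (lam - 1) * sum(sign(v) * log1p(|v|)).
    """
    n = len(v)
    pos = v >= 0
    log1p_abs = np.log1p(np.abs(v))
    penalty_sum = (np.sign(v) * log1p_abs).sum()
    lam = _LAMBDA_GRID[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y_pos = np.where(lam == 0.0, log1p_abs[None, :],
                         np.expm1(lam * log1p_abs[None, :])
                         / np.where(lam == 0.0, 1.0, lam))
        two_ml = 2.0 - lam
        y_neg = np.where(lam == 2.0, -log1p_abs[None, :],
                         -np.expm1(two_ml * log1p_abs[None, :])
                         / np.where(lam == 2.0, 1.0, two_ml))
        y = np.where(pos[None, :], y_pos, y_neg)
        var = y.var(axis=1)
        llf = -n / 2.0 * np.log(var) + (_LAMBDA_GRID - 1.0) * penalty_sum
    llf[~np.isfinite(llf)] = -np.inf
    return llf


def _fit_power_lambda(v: np.ndarray, kind: str) -> float:
    """Profile-ML lambda over the fixed grid; first grid point wins ties."""
    lls = _boxcox_grid_llf(v) if kind == "box_cox" else _yeojohnson_grid_llf(v)
    return float(_LAMBDA_GRID[int(np.argmax(lls))])


def _sentinel(name: str, reason: str) -> TransformReport:
    report = TransformReport(transform_name=name, p_statistic=math.inf,
                             dof=0, ratio=math.inf)
    report.parameters["reason"] = reason
    return report


def apply_transform(values, name: str) -> TransformReport:
    """Fit one named transform and score its output for normality.

    Requires at least 10 non-missing values.  For ``log`` and ``box_cox``
    the data must be strictly positive; otherwise a sentinel report with
    ratio = +inf is returned (never an exception).
    """
    if name not in TRANSFORM_NAMES:
        raise ValueError(f"unknown transform {name!r}; choose from {TRANSFORM_NAMES}")
    v = _clean(values)
    if len(v) < 10:
        raise ValueError(f"need at least 10 non-missing values, got {len(v)}")

    params: dict[str, float] = {}
    if name == "identity":
        out = v.copy()
    elif name == "log":
        if (v <= 0).any():
            return _sentinel(name, "non-positive values")
        out = np.log(v)
    elif name == "box_cox":
        if (v <= 0).any():
            return _sentinel(name, "non-positive values")
        lam = _fit_power_lambda(v, "box_cox")
        out = stats.boxcox(v, lmbda=lam)
        params["lambda"] = lam
    elif name == "yeo_johnson":
        lam = _fit_power_lambda(v, "yeo_johnson")
        out = stats.yeojohnson(v, lmbda=lam)
        params["lambda"] = lam
    else:  # ordered_quantile
        out = ordered_quantile_scores(v)

    try:
        p_stat, dof, ratio = pearson_normality_ratio(out)
    except DegenerateVariableError:
        # a transform that collapses the sample is useless, not an error
        return _sentinel(name, "transform collapsed the sample")
    return TransformReport(transform_name=name, parameters=params,
                           p_statistic=p_stat, dof=dof, ratio=ratio,
                           transformed_values=np.asarray(out, dtype=float))


def select_transform(values, candidates=TRANSFORM_NAMES) -> TransformReport:
    """Evaluate every candidate and return the minimal-ratio report.

    Ties break by the fixed precedence identity > log > box_cox >
    yeo_johnson > ordered_quantile (prefer the simpler transform).
    Identity and ordered-quantile always apply, so a winner always exists.
    """
    best: TransformReport | None = None
    for name in candidates:
        report = apply_transform(values, name)
        if best is None or report.ratio < best.ratio:
            best = report
    if best is None or not best.applicable:
        raise ValueError("no applicable transform found")
    return best
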