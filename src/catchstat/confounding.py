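"""Confounder screening, the 10% change-in-estimate rule, and adjusted
correlation.

A confounder is a variable associated with both the exposure (secondary
variable) and the outcome (primary variable) that distorts their crude
association.  Detection is two-step:

1. *Screening*: a candidate survives when its correlation magnitude with
   BOTH the primary and the secondary variable reaches a threshold
   (default |r| >= 0.3) — the correlation-matrix inspection step.
2. *Change-in-estimate*: refit the single-variable linear model
   primary ~ secondary with the screened candidates added jointly; if the
   secondary's coefficient moves by more than 10% in absolute relative
   terms, confounding is declared.

The adjusted association is then reported as the partial correlation of
primary and secondary given the confounder set: both are residualized on
the confounders by least squares (with intercept) and the residuals are
correlated, with degrees of freedom reduced by k = |confounders| in the
t statistic and Fisher-z interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable
from .univariate import (LABEL_ADJUSTED, CorrelationResult, _complete_pairs,
                         _pearson_r, correlation_inference, correlation_test)

CHANGE_THRESHOLD_PCT = 10.0
SCREEN_THRESHOLD_R = 0.3


@dataclass
class CandidateAssessment:
    """Per-candidate screening and one-at-a-time adjustment diagnostics."""

    name: str
    cor_with_primary: float
    cor_with_secondary: float
    screened: bool
    beta_adjusted_solo: float | None = None
    percent_change_solo: float | None = None


@dataclass
class ConfounderReport:
    """Outcome of the full confounding assessment."""

    primary: str
    secondary: str
    candidates: list[CandidateAssessment]
    correlation_matrix: pd.DataFrame
    beta_crude: float
    beta_adjusted: float
    percent_change: float
    flagged: bool
    confounder_set: list[str]
    adjusted_result: CorrelationResult

    def to_json(self) -> str:
        def _plain(obj):
            if isinstance(obj, np.generic):
                return obj.item()
            raise TypeError(f"not JSON serializable: {type(obj)}")
        return json.dumps({
            "primary": self.primary, "secondary": self.secondary,
            "candidates": [vars(c) for c in self.candidates],
            "correlation_matrix": self.correlation_matrix.to_dict(),
            "beta_crude": self.beta_crude,
            "beta_adjusted": self.beta_adjusted,
            "percent_change": self.percent_change,
            "flagged": self.flagged,
            "confounder_set": self.confounder_set,
            "adjusted_result": self.adjusted_result.to_dict(),
        }, indent=2, default=_plain)


def screen_candidates(
    table: CommunityTable, primary: str, secondary: str,
    candidates: list[str], threshold: float = SCREEN_THRESHOLD_R,
) -> list[str]:
    """Candidates correlated (|r| >= threshold) with BOTH primary and
    secondary, in input order.  Pairwise-complete correlations."""
    kept = []
    for cand in candidates:
        if cand in (primary, secondary):
            raise ValueError(f"candidate {cand!r} duplicates an analysis variable")
        r_p = _pairwise_r(table, cand, primary)
        r_s = _pairwise_r(table, cand, secondary)
        if abs(r_p) >= threshold and abs(r_s) >= threshold:
            kept.append(cand)
    return kept


def _pairwise_r(table: CommunityTable, a: str, b: str) -> float:
    x, y = _complete_pairs(table.data[a].to_numpy(dtype=float),
                           table.data[b].to_numpy(dtype=float))
    return _pearson_r(x, y)


def coefficient_change(beta_crude: float, beta_adjusted: float,
                       threshold_pct: float = CHANGE_THRESHOLD_PCT
                       ) -> tuple[float, bool]:
    """Absolute percent change in the exposure coefficient and the flag.

    Uses absolute values so a sign flip always flags.
    """
    if beta_crude == 0:
        raise ValueError("crude effect is zero; percent change undefined")
    pct = 100.0 * abs(beta_adjusted - beta_crude) / abs(beta_crude)
    return float(pct), bool(pct > threshold_pct)


def _ols_coefficients(y: np.ndarray, X: np.ndarray,
                      names: list[str]) -> np.ndarray:
    """Least-squares coefficients with intercept; errors on rank deficiency
    naming the dependent columns."""
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dependent = _dependent_columns(design, ["(intercept)"] + names)
        raise ValueError(f"collinear regressors: {dependent}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def _dependent_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (QR pivot diagnostics)."""
    from scipy.linalg import qr
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def partial_correlation(x, y, z, *, method: str = "pearson",
                        names: list[str] | None = None) -> CorrelationResult:
    """Correlation of x and y after removing a set z of controls from both.

    x and y are each residualized on z (least squares with intercept); the
    Pearson correlation of the residuals is reported with n - 2 - k
    degrees of freedom (k = number of controls) and the matching Fisher-z
    interval.  With z empty this reduces exactly to ``correlation_test``.
    """
    z = [np.asarray(col, dtype=float) for col in z]
    if not z:
        return correlation_test(x, y, method=method, label=LABEL_ADJUSTED)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack(z)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Z).all(axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    k = Z.shape[1]
    n = len(x)
    if n < k + 5:
        raise ValueError(f"need at least {k + 5} complete cases, got {n}")
    znames = names if names is not None else [f"z{j}" for j in range(k)]
    bx = _ols_coefficients(x, Z, znames)
    by = _ols_coefficients(y, Z, znames)
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ bx
    ry = y - design @ by
    r = _pearson_r(rx, ry)
    return correlation_inference(r, n, k=k, method=method, label=LABEL_ADJUSTED)


def assess_confounding(
    table: CommunityTable, primary: str, secondary: str,
    metadata: list[str], *, screen_threshold: float = SCREEN_THRESHOLD_R,
    change_threshold_pct: float = CHANGE_THRESHOLD_PCT,
) -> ConfounderReport:
    """Full confounding assessment over candidate metadata columns.

    Fits primary ~ secondary (crude), adds the screened candidates jointly
    (adjusted), applies the change-in-estimate rule, and — when flagged —
    reports the partial correlation given the screened set as the
    "Confounding Removed" row.  Expects variables already transformed and
    cleaned by the upstream pipeline.
    """
    involved = [primary, secondary] + list(metadata)
    for var in involved:
        if var not in table.numeric_vars:
            raise ValueError(f"variable {var!r} is absent or not numeric")
    df = table.data[involved].dropna()
    n = len(df)
    if n < len(involved) + 5:
        raise ValueError(f"only {n} complete cases over {involved}")

    corr_matrix = df.corr(method="pearson")
    y = df[primary].to_numpy(dtype=float)
    x = df[secondary].to_numpy(dtype=float)
    beta_crude = _ols_coefficients(y, x[:, None], [secondary])[1]
    if beta_crude == 0:
        raise ValueError("degenerate crude model: zero crude coefficient")

    screened = screen_candidates(table, primary, secondary, list(metadata),
                                 threshold=screen_threshold)
    candidates = []
    for cand in metadata:
        r_p = float(corr_matrix.loc[cand, primary])
        r_s = float(corr_matrix.loc[cand, secondary])
        assessment = CandidateAssessment(
            name=cand, cor_with_primary=r_p, cor_with_secondary=r_s,
            screened=cand in screened)
        X_solo = df[[secondary, cand]].to_numpy(dtype=float)
        beta_solo = _ols_coefficients(y, X_solo, [secondary, cand])[1]
        assessment.beta_adjusted_solo = float(beta_solo)
        assessment.percent_change_solo = coefficient_change(
            beta_crude, beta_solo, change_threshold_pct)[0]
        candidates.append(assessment)

    if screened:
        X_adj = df[[secondary] + screened].to_numpy(dtype=float)
        beta_adjusted = _ols_coefficients(y, X_adj, [secondary] + screened)[1]
        percent_change, flagged = coefficient_change(
            beta_crude, beta_adjusted, change_threshold_pct)
    else:
        beta_adjusted, percent_change, flagged = beta_crude, 0.0, False

    confounder_set = screened if flagged else []
    if confounder_set:
        adjusted = partial_correlation(
            x, y, [df[c].to_numpy(dtype=float) for c in confounder_set],
            names=confounder_set)
    else:
        adjusted = correlation_test(x, y, label=LABEL_ADJUSTED)

    return ConfounderReport(
        primary=primary, secondary=secondary, candidates=candidates,
        correlation_matrix=corr_matrix, beta_crude=float(beta_crude),
        beta_adjusted=float(beta_adjusted), percent_change=float(percent_change),
        flagged=flagged, confounder_set=confounder_set,
        adjusted_result=adjusted)
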