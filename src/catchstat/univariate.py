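"""Univariate correlation analysis, raw and via the full statistical pipeline.

The central report is a correlation coefficient with its t statistic,
two-sided p value and Fisher-z 95% confidence interval:

    t  = r * sqrt((n - 2 - k) / (1 - r^2))        (k variables partialled out)
    CI = tanh(atanh(r) +- 1.96 / sqrt(n - 3 - k))

with k = 0 here (the confounding module reuses the same machinery with
k > 0).  Spearman's coefficient is Pearson's applied to average ranks; its
p value uses the same t approximation, adequate at community-area sample
sizes (n ~ 77).

``correlate_intelligent`` reproduces the two-row "raw vs. statistical
intelligence" comparison: the raw correlation on untouched pairs, and the
pipeline correlation after per-variable normality-transform selection and
IQR outlier removal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cleaning import CleaningReport, remove_outliers
from .io import CommunityTable
from .normalize import DegenerateVariableError, TransformReport, select_transform

METHODS = ("pearson", "spearman")

LABEL_RAW = "Raw Data"
LABEL_INTELLIGENT = "Using Statistical Intelligence"
LABEL_ADJUSTED = "Confounding Removed"


@dataclass
class CorrelationResult:
    """One correlation-table row: r with its inference quantities."""

    method: str
    label: str
    r: float
    n_effective: int
    t_statistic: float
    p_value: float
    ci95: tuple[float, float]
    k_adjusted: int = 0

    @property
    def method_display(self) -> str:
        return {"pearson": "Pearson's product-moment correlation",
                "spearman": "Spearman's rank correlation"}[self.method]

    def to_dict(self) -> dict:
        return {
            "method": self.method, "label": self.label, "r": float(self.r),
            "n_effective": int(self.n_effective), "t": float(self.t_statistic),
            "p_value": float(self.p_value),
            "ci95": [float(v) for v in self.ci95],
            "k_adjusted": int(self.k_adjusted),
        }


def correlation_inference(
    r: float, n: int, *, k: int = 0, method: str = "pearson",
    label: str = LABEL_RAW,
) -> CorrelationResult:
    """Build a CorrelationResult from r and the effective sample size.

    ``k`` counts variables partialled out: the t statistic uses n - 2 - k
    degrees of freedom and the Fisher-z interval uses sqrt(n - 3 - k).
    """
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:  # exact collinearity up to float rounding
        r = math.copysign(1.0, r)
    dof = n - 2 - k
    if dof < 1:
        raise ValueError(f"not enough observations (n={n}, k={k})")
    if abs(r) == 1.0:
        t, p = math.copysign(math.inf, r), 0.0
        ci = (r, r)
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), dof)
        half = 1.96 / math.sqrt(n - 3 - k)
        z = math.atanh(r)
        ci = (math.tanh(z - half), math.tanh(z + half))
    return CorrelationResult(method=method, label=label, r=r, n_effective=n,
                             t_statistic=t, p_value=p, ci95=ci, k_adjusted=k)


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt((xc * xc).sum())
    sy = math.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise DegenerateVariableError("degenerate variable: zero variance")
    return float((xc * yc).sum() / (sx * sy))


def correlation_test(x, y, method: str = "pearson",
                     label: str = LABEL_RAW) -> CorrelationResult:
    """Correlation between paired vectors with t test and Fisher-z CI.

    Pairs with any missing value are dropped (listwise); at least 5
    complete pairs are required.  ``spearman`` is Pearson on average ranks.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 complete pairs, got {n}")
    if method == "spearman":
        x = stats.rankdata(x, method="average")
        y = stats.rankdata(y, method="average")
    r = _pearson_r(x, y)
    return correlation_inference(r, n, method=method, label=label)


@dataclass
class IntelligentCorrelation:
    """Raw vs. pipeline correlation with the pipeline's audit trail."""

    raw: CorrelationResult
    intelligent: CorrelationResult
    transforms: dict[str, TransformReport] = field(default_factory=dict)
    cleaning: CleaningReport | None = None

    def to_json(self) -> str:
        return json.dumps({
            "raw": self.raw.to_dict(),
            "intelligent": self.intelligent.to_dict(),
            "transforms": {k: v.to_dict() for k, v in self.transforms.items()},
            "cleaning": None if self.cleaning is None
            else json.loads(self.cleaning.to_json()),
        }, indent=2)


def transform_and_clean(
    table: CommunityTable, variables: list[str]
) -> tuple[CommunityTable, dict[str, TransformReport], CleaningReport]:
    """The shared preprocessing pipeline: listwise-complete rows over
    ``variables``, best normality transform per variable, then one pass of
    IQR outlier removal across all of them."""
    df = table.data[variables].dropna()
    if df.empty:
        raise ValueError("no complete rows over the requested variables")
    sub = CommunityTable(df)
    transforms: dict[str, TransformReport] = {}
    out = sub.data.copy()
    for var in variables:
        report = select_transform(out[var].to_numpy(dtype=float))
        transforms[var] = report
        out[var] = report.transformed_values
    transformed = CommunityTable(out)
    cleaned, cleaning = remove_outliers(transformed, variables)
    return cleaned, transforms, cleaning


def correlate_intelligent(
    table: CommunityTable, primary: str, secondary: str,
    method: str = "pearson",
) -> IntelligentCorrelation:
    """Raw correlation and the transform->clean->correlate pipeline result.

    Both results use listwise-complete pairs of (primary, secondary); the
    intelligent row re-selects the best normality transform per variable
    and removes IQR outliers before correlating.
    """
    for var in (primary, secondary):
        if var not in table.numeric_vars:
            raise ValueError(f"variable {var!r} is absent or not numeric")
    pairs = table.data[[primary, secondary]].dropna()
    raw = correlation_test(pairs[primary], pairs[secondary], method=method,
                           label=LABEL_RAW)
    cleaned, transforms, cleaning = transform_and_clean(
        table, [primary, secondary])
    intelligent = correlation_test(
        cleaned.data[primary], cleaned.data[secondary], method=method,
        label=LABEL_INTELLIGENT)
    return IntelligentCorrelation(raw=raw, intelligent=intelligent,
                                  transforms=transforms, cleaning=cleaning)


def format_correlation_table(results: list[CorrelationResult]) -> str:
    """Render results in the standard report layout
    (Method | Label | Correlation | 95% CI | t | p-value)."""
    rows = [("Method", "Label", "Correlation", "95% CI", "t", "p-value")]
    for res in results:
        rows.append((
            res.method_display, res.label, f"{res.r:.3f}",
            f"[{res.ci95[0]:.3f} {res.ci95[1]:.3f}]",
            f"{res.t_statistic:.3f}", f"{res.p_value:.4f}",
        ))
    widths = [max(len(row[i]) for row in rows) for i in range(6)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths))
             for row in rows]
    return "\n".join(lines)
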