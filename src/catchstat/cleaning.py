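"""Outlier removal by the 1.5x IQR fence rule.

Quartiles use linear interpolation of order statistics (type-7, the
default of numpy/R).  A row is removed when any analysis variable lies
strictly outside its fences; values exactly on a fence are kept.  Fences
are computed once on the pre-removal data (single pass, no iteration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class VariableFences:
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


@dataclass
class CleaningReport:
    """Per-variable fences plus the kept/removed region-id partition."""

    fences: dict[str, VariableFences] = field(default_factory=dict)
    kept_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "fences": {k: vars(v) for k, v in self.fences.items()},
            "kept_ids": self.kept_ids,
            "removed_ids": self.removed_ids,
        }, indent=2)


def iqr_fences(values) -> VariableFences:
    """Type-7 quartiles and the [Q1 - 1.5*IQR, Q3 + 1.5*IQR] fences.

    Requires at least 4 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        raise ValueError(f"need at least 4 non-missing values, got {len(v)}")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation = type-7
    iqr = q3 - q1
    return VariableFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                          lower_fence=float(q1 - 1.5 * iqr),
                          upper_fence=float(q3 + 1.5 * iqr))


def remove_outliers(
    table: CommunityTable, variables: list[str]
) -> tuple[CommunityTable, CleaningReport]:
    """Drop rows with any listed variable strictly outside its IQR fences.

    Fences are computed on the pre-removal data; missing values never
    flag a row.  Surviving rows keep their original order.

    Raises
    ------
    ValueError
        If a listed variable is absent/non-numeric, or cleaning would
        remove every row.
    """
    numeric = set(table.numeric_vars)
    for var in variables:
        if var not in table.data.columns:
            raise ValueError(f"unknown variable {var!r}")
        if var not in numeric:
            raise ValueError(f"variable {var!r} is not numeric")

    report = CleaningReport()
    outside = np.zeros(len(table), dtype=bool)
    for var in variables:
        col = table.data[var].to_numpy(dtype=float)
        fences = iqr_fences(col)
        report.fences[var] = fences
        with np.errstate(invalid="ignore"):
            # NaN compares False on both sides, so missing never flags
            outside |= (col < fences.lower_fence) | (col > fences.upper_fence)

    ids = np.asarray(table.region_ids)
    report.removed_ids = list(ids[outside])
    report.kept_ids = list(ids[~outside])
    if not report.kept_ids:
        raise ValueError("cleaning annihilated dataset: all rows removed")
    for rid in report.removed_ids:
        logger.info("removed outlier row %s", rid)
    cleaned = CommunityTable(table.data.loc[report.kept_ids])
    return cleaned, report
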