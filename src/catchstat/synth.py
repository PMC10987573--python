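"""Synthetic community tables with known statistical structure.

Real catchment-area tables (SDOH covariates vs. health outcomes over ~77
community areas) are correlated, skewed, and occasionally contaminated by
gross recording errors.  The generators here emulate those features with
known ground truth: a latent Gaussian copula supplies the correlation
structure, monotone marginal distortions supply the skew, and seeded
per-cell displacement supplies outliers.  A dedicated confounding scenario
generates the textbook exposure/outcome/confounder triangle so the full
adjustment pipeline can be tested against closed-form population values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io import BoundarySet, CommunityTable

_MARGINALS = ("identity", "exponential", "logistic-squash")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic community table.

    Parameters
    ----------
    n_regions : int
        Number of rows (regions).
    variables : list of str
        Unique variable names; order fixes the correlation-matrix order.
    latent_correlation : array-like
        Symmetric PSD correlation matrix (unit diagonal) of the latent
        Gaussian variables.
    marginal_map : dict, optional
        Per-variable monotone distortion applied after correlating:
        ``identity`` (default), ``exponential`` (exp of the latent z, a
        log-normal margin), or ``logistic-squash`` (1/(1+exp(-z))).
    outlier_rate : float
        Fraction of cells displaced, in [0, 0.2].
    outlier_magnitude : float
        Displacement size in multiples of the column IQR.
    seed : int
        Seed for all randomness.
    """

    n_regions: int
    variables: list[str]
    latent_correlation: np.ndarray
    marginal_map: dict[str, str] = field(default_factory=dict)
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        R = np.asarray(self.latent_correlation, dtype=float)
        p = len(self.variables)
        if R.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        lam_min = float(np.linalg.eigvalsh(R).min())
        if lam_min < -1e-10:
            raise ValueError(
                f"correlation matrix is not PSD: smallest eigenvalue {lam_min:.6g}")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError("outlier_rate must lie in [0, 0.2]")
        for name, kind in self.marginal_map.items():
            if name not in self.variables:
                raise ValueError(f"marginal_map names unknown variable {name!r}")
            if kind not in _MARGINALS:
                raise ValueError(f"unknown marginal {kind!r}; choose from {_MARGINALS}")
        self.latent_correlation = R

    def to_json(self) -> str:
        d = asdict(self)
        d["latent_correlation"] = self.latent_correlation.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


@dataclass
class ConfoundingScenario:
    """Pure exposure/outcome/confounder generating model.

    The confounder C is standard normal; the secondary (exposure)
    X = beta_xc*C + e1 and the primary (outcome)
    Y = beta_yc*C + beta_xy_direct*X + e2, with independent Gaussian noise
    of scale ``noise_sd``.  With beta_xy_direct = 0 the crude X-Y
    correlation is entirely confounded and the population partial
    correlation given C is exactly zero.
    """

    n: int = 200
    beta_xc: float = 1.0
    beta_yc: float = 1.0
    beta_xy_direct: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def population_crude_correlation(self) -> float:
        """Closed-form population cor(X, Y) under the generating model."""
        b_xc, b_yc, b_xy, s = (self.beta_xc, self.beta_yc,
                               self.beta_xy_direct, self.noise_sd)
        var_x = b_xc ** 2 + s ** 2
        cov_xy = b_yc * b_xc + b_xy * var_x
        var_y = b_yc ** 2 + b_xy ** 2 * var_x + 2 * b_xy * b_yc * b_xc + s ** 2
        return cov_xy / np.sqrt(var_x * var_y)

    def population_partial_correlation(self) -> float:
        """Population cor(X, Y | C); zero iff beta_xy_direct is zero."""
        b_xy, s = self.beta_xy_direct, self.noise_sd
        return b_xy * s / np.sqrt((b_xy ** 2 + 1) * s ** 2)


def _region_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


def _distort(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "identity":
        return z
    if kind == "exponential":
        return np.exp(z)
    if kind == "logistic-squash":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown marginal {kind!r}")


def generate_table(spec: SyntheticSpec) -> CommunityTable:
    """Draw a community table from the latent-Gaussian copula model.

    Rows are multivariate normal with ``spec.latent_correlation``, marginals
    are distorted per ``spec.marginal_map`` (monotone, so rank structure is
    preserved), then ``outlier_rate`` of cells are displaced by
    ``outlier_magnitude`` column-IQRs in a seeded random direction.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.variables)
    z = rng.multivariate_normal(
        np.zeros(p), spec.latent_correlation, size=spec.n_regions, method="eigh")
    cols = {}
    for j, name in enumerate(spec.variables):
        kind = spec.marginal_map.get(name, "identity")
        cols[name] = _distort(z[:, j], kind)
    df = pd.DataFrame(cols, index=_region_ids(spec.n_regions))

    if spec.outlier_rate > 0:
        n_cells = spec.n_regions * p
        n_out = int(round(spec.outlier_rate * n_cells))
        flat = rng.choice(n_cells, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        values = df.to_numpy()
        q1 = np.percentile(values, 25, axis=0)
        q3 = np.percentile(values, 75, axis=0)
        iqr = q3 - q1
        rows, colidx = np.unravel_index(flat, (spec.n_regions, p))
        values[rows, colidx] += signs * spec.outlier_magnitude * iqr[colidx]
        df = pd.DataFrame(values, columns=df.columns, index=df.index)

    return CommunityTable(df)


def confounding_scenario(
    s: ConfoundingScenario, n_nuisance: int = 2
) -> tuple[CommunityTable, dict]:
    """Generate the confounding-triangle table plus its ground truth.

    Returns the table with columns ``primary``, ``secondary``,
    ``confounder`` and ``n_nuisance`` independent standard-normal nuisance
    columns, together with the generating parameters and the closed-form
    population crude/partial correlations.
    """
    rng = np.random.default_rng(s.seed)
    c = rng.standard_normal(s.n)
    x = s.beta_xc * c + s.noise_sd * rng.standard_normal(s.n)
    y = (s.beta_yc * c + s.beta_xy_direct * x
         + s.noise_sd * rng.standard_normal(s.n))
    cols = {"primary": y, "secondary": x, "confounder": c}
    for k in range(n_nuisance):
        cols[f"nuisance{k + 1}"] = rng.standard_normal(s.n)
    table = CommunityTable(pd.DataFrame(cols, index=_region_ids(s.n)))
    truth = {
        "beta_xc": s.beta_xc,
        "beta_yc": s.beta_yc,
        "beta_xy_direct": s.beta_xy_direct,
        "noise_sd": s.noise_sd,
        "population_crude_r": s.population_crude_correlation(),
        "population_partial_r": s.population_partial_correlation(),
    }
    return table, truth


def generate_boundaries(n: int) -> BoundarySet:
    """A ceil(sqrt(n)) x ceil(sqrt(n)) grid of unit squares, first n cells.

    Ids match :func:`generate_table` ("R001", "R002", ...); geometry is in
    abstract grid units, adequate for exercising the mapping layer.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    side = int(np.ceil(np.sqrt(n)))
    ids = _region_ids(n)
    geoms = {}
    for i in range(n):
        row, col = divmod(i, side)
        geoms[ids[i]] = box(col, row, col + 1, row + 1)
    return BoundarySet(geoms)
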