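# Methods

This note records the statistical model behind `catchstat`, the defaults
and numerical conventions it fixes, and what the synthetic-data generator
does and does not emulate.

## Data model

The unit of analysis is a *community table*: one row per geographic region
(a community area, census tract, county...), keyed by an opaque string id,
with numeric columns (rates, percentages, counts) and optional categorical
columns. Regions are treated as independent samples; no spatial
autocorrelation structure is modelled, matching the analysis the package
implements. Boundaries are WGS84 polygons joined by the same id.

On CSV read, blank/`NA`/`NaN` cells (case-insensitive) are missing. A
column is typed numeric when at least half of its non-missing cells parse
as numbers; unparseable cells in a numeric column become missing, so a
stray annotation does not silently demote a rate column to categorical.
Floats are parsed with the correctly-rounded parser so a write/read cycle
is bit-exact. Missingness is handled listwise *per analysis* (only the
variables entering that analysis need to be present), which maximizes the
effective n of each report at the cost of reports using slightly different
row sets — the trade chosen deliberately for small-n region tables.

## Normality-transform selection

Candidates: identity, log, Box–Cox, Yeo–Johnson, ordered-quantile normal
scores (rank i of n → Φ⁻¹((i−0.5)/n), average ranks for ties). Each
candidate's output is scored by the Pearson chi-square goodness-of-fit
statistic divided by its degrees of freedom, and the minimal ratio wins;
ties break toward the simpler transform in the listed order.

The Pearson statistic uses k = ⌈2·n^0.4⌉ classes of equal probability
under Normal(μ̂, σ̂) fitted to the sample (σ̂ with ddof = 1), so the
expected count per class is n/k, and df = k − 3 (k − 1 minus the two
estimated parameters). This is the standard chi-square-test convention;
with it, a genuinely normal sample has E[P/df] ≈ 1, which the tests verify
empirically.

Box–Cox and Yeo–Johnson λ are fitted by profile maximum likelihood on the
fixed grid [−5, 5] in steps of 0.01. The grid search is vectorized over
the whole grid, deterministic, and agrees with scipy's Brent-based
optimizer to within one grid step on test data. Box–Cox and log require
strictly positive data; on non-positive input they yield a sentinel report
with ratio = +∞ rather than an exception, so the selection loop always
completes (identity and ordered-quantile apply to anything non-degenerate).
A transform is fitted on the analysis sample itself — there is no
train/apply split, because the object of inference is the same sample.

The Lambert W×F family is not in the candidate set: it has no agreed
single parameterization at this level, and its practical effect on heavy
tails overlaps the ordered-quantile transform. The candidate registry is a
tuple; adding a transform means adding a branch in `apply_transform`.

## Outlier cleaning

Fences are Q1 − 1.5·IQR and Q3 + 1.5·IQR with type-7 (linear
interpolation) quartiles — the numpy/R default, fixed here as the testable
convention. A row is removed when **any** analysis variable lies strictly
outside its fences; values exactly on a fence are kept ("outside the
range" read strictly). Fences are computed once on the pre-removal data:
the pass is not iterated, so a second application could remove more rows —
the pipeline never reapplies it. Missing values never flag a row. Cleaning
runs *after* transformation, on the transformed values. Removing every row
is an error, not an empty result.

## Correlation reports

All correlation rows carry the same inference machinery: for r on n
complete pairs with k variables partialled out,

    t  = r·√((n − 2 − k)/(1 − r²)),  two-sided p on n − 2 − k df,
    CI = tanh(atanh r ± 1.96/√(n − 3 − k)).

The interval uses the normal 1.96 rather than a t quantile — this exactly
reproduces the published report format the package mirrors. Spearman's
coefficient is Pearson on average ranks, with the same t approximation
(adequate at n ≈ 77; an exact permutation test would change nothing at
these sizes). |r| within 1e−12 of 1 is snapped to ±1 so exact collinearity
reports r = 1, p = 0, CI = [1, 1] instead of floating-point residue.

## Confounding

Detection is deliberately two-step, and both steps must fire:

1. **Screening**: candidate c survives iff |cor(c, primary)| ≥ 0.3 and
   |cor(c, secondary)| ≥ 0.3 (pairwise-complete Pearson). The 0.3 default
   is the conventional "moderate correlation" bar; it is a parameter.
2. **Change in estimate**: the exposure coefficient from
   primary ~ secondary is compared with the same coefficient after adding
   all screened candidates jointly;
   percent change = 100·|β_adj − β_crude|/|β_crude| > 10% flags
   confounding. Absolute values make a sign flip always flag. Per-candidate
   one-at-a-time changes are reported for transparency, but the decision
   uses the joint model.

The adjusted association is the partial correlation: residualize both
variables on the confounder set by least squares with intercept and
correlate the residuals, with df reduced by k in t and CI. This is the one
standard construction that yields the same r/CI/t/p report shape as the
crude row; with an empty set it reduces bit-exactly to the plain
correlation. Rank-deficient control sets raise an error naming the
dependent columns.

## Multivariate models and importance

All variables are standardized (mean 0, sd 1, ddof = 1) after the
transform/clean pipeline, so coefficients are unit-comparable.
A feature's importance is its percent contribution
100·|β_k|/Σ_j|β_j| over the non-intercept coefficients; contributions sum
to 100 whenever any coefficient is nonzero, and ranking is descending with
stable ties. Display rounding is one decimal, half away from zero.

* **OLS** (statsmodels): t and two-sided p on n − p − 1 df, adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
* **Logistic** (statsmodels, Newton/IRLS, tol 1e−8, ≤100 iterations): Wald
  z and p. Non-convergence, non-finite estimates, or |β| > 1e4 are
  reported as (quasi-)separation with a pointer toward regularization.
* **Lasso** (in-package coordinate descent): objective
  (1/(2n))·‖y − Xβ‖² + λ‖β‖₁ on standardized features and centered y,
  coordinate updates to max |Δβ| < 1e−7. λ ≥ λ_max = max_j |Xjᵀy|/n
  short-circuits to the exact all-zero solution. The default λ is chosen
  by 5-fold cross-validation over a 50-point log grid spanning
  [λ_max/1000, λ_max] with seeded fold assignment. No t/p values are
  attached: naive post-selection inference is invalid, and the package
  declines to print it.

Auto-selection: a ≤2-valued outcome → logistic; p ≥ n/2 or any pairwise
secondary |r| > 0.9 → lasso; otherwise OLS. The choice and its reason are
logged. Gradient boosting and neural networks exist in the model registry
only as named entries that raise `NotImplementedError`: no architecture,
loss, or hyperparameters are defined for them here, and inventing them
would produce untestable results.

## Mapping

Numeric choropleths interpolate linearly in RGB between a light and a dark
endpoint (default lavender `#EFEDF5` → purple `#3F007D`, darker = higher)
over the observed min–max; interpolation space is a cosmetic choice.
Out-of-domain values clamp with a logged warning; a constant variable maps
to the mid-scale color with a "degenerate range" warning; missing regions
get neutral grey and a legend entry. Categorical variables cycle a fixed
8-color palette. The SVG is assembled from formatted strings with fixed
precision, so identical inputs give byte-identical files — that is the
tested surface; the HTML output just embeds the same SVG. Linear min–max
scaling (not quantile bins) keeps the legend a continuous spectrum.

## Synthetic data

`generate_table` draws a latent multivariate normal with a user-supplied
correlation matrix (PSD required; the error reports the smallest
eigenvalue), then distorts marginals monotonically (identity, exponential,
logistic squash) — a Gaussian copula, so rank structure and therefore the
latent correlation survive the distortion and ground truth stays known.
Outliers are then injected per cell (matching the per-variable fence
cleaning): a seeded choice of round(rate·n·p) cells is displaced by
±magnitude·IQR of its column. Everything is reproducible from the seed.

`confounding_scenario` generates C ~ N(0,1), X = β_xc·C + σε₁,
Y = β_yc·C + β_xy·X + σε₂ plus independent nuisance columns, and returns
closed-form population crude and partial correlations alongside. Defaults
(n = 200, unit effects, σ = 1, no direct effect) give population crude
r = 0.5 against a true partial r of 0 — a regime where the reversal is
detectable but not trivial at region-table sample sizes. One caution the
algebra forces: with β_xc = 0 the *coefficient* of X is unconfounded, but
the partial correlation still differs from the crude one whenever β_yc ≠ 0,
because conditioning on C removes variance from Y.

What the generator does **not** emulate: spatial autocorrelation, realistic
Chicago geography (boundaries are a unit-square grid), missing-data
mechanisms, or measurement error correlated with region size. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generating models, not robustness to spatially structured
real-world data.

## Problem sizes and numerical choices

The test suite and the reproduction script use n = 200–1000 per draw, 100
seeds for Monte-Carlo rates, and 200 replicates for CI coverage — sizes at
which every Monte-Carlo band asserted is comfortably stable while the
whole suite stays fast. The λ grid (1001 points), the coordinate-descent
tolerance (1e−7), and the IRLS tolerance (1e−8) are fixed rather than
adaptive so results are deterministic across platforms. Degenerate inputs
fail loudly by design: zero-variance variables, all-rows-removed cleaning,
single-class logistic outcomes, rank-deficient designs, and zero crude
coefficients in the change-in-estimate rule all raise errors naming the
offending quantity.
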