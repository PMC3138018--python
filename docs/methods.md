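# Methods

`pmbme` implements a two-stage scheme for mapping monthly fine particulate
matter (PM2.5) over a city from a network in which only some stations
measure PM2.5 while more measure PM10, plus a cadastral landuse layer.

## Model

Write `X_{s,t}` and `Y_{s,t}` for the monthly PM2.5 and PM10 concentrations
at location `s` and month `t`, both treated as spatiotemporal random
fields, and `r_{s,t} = X_{s,t} / Y_{s,t}` for the fine-to-coarse ratio.

**Stage 1 — ratio land-use regression.** The ratio is regressed on the
areas (m²) of landuse classes intersected with concentric ring buffers
around each station (0–50, 50–100, 100–300, 300–500, 500–1000 m; half-open
annuli `(inner, outer]`). Regressors are chosen by forward-entry /
backward-removal stepwise selection on partial-F statistics with
variance-inflation-factor screening (`VIF <= 10`); ring features of a
class are strongly collinear, so the later-entering member of a collinear
pair is rejected. The fitted model yields a ratio prediction `r̂` and a
standard deviation `SD(r̂)` at any point; multiplied by PM10 this gives an
*uncertain trend* `m = r̂·Y` for PM2.5.

**Stage 2 — Bayesian Maximum Entropy residual estimation.** PM2.5
residuals about the trend are modelled as a zero-mean field with the nested
exponential space-time covariance

    c(h, τ) = c0·exp(−3h/a_r1)·exp(−3τ/a_t1) + c1·exp(−3h/a_r2)·exp(−3τ/a_t2)

(`h` km, `τ` months; each `a` is a *practical range*: the structure's
correlation falls to e⁻³ ≈ 5% at lag `a`). At stations observing PM2.5 the
residual `X_obs − m` is *hard* (exact) evidence; elsewhere the ratio
uncertainty produces *soft interval* evidence: the ratio is taken uniform
on `⌊r̂ − SD(r̂), r̂ + SD(r̂)⌋` (clamped to `[0.01, 1]`, since PM2.5 cannot
exceed PM10), hence the residual lies in `[l·Y − m, u·Y − m]`. With
general knowledge limited to a mean and covariance, the maximum-entropy
prior is Gaussian, and the BME posterior at an estimation point is

    f_K(x) ∝ f_G(x | hard) · P(soft ∈ ∏[l_i, u_i] | hard, x),

carried on an explicit quadrature grid with its normalization constant.
Simple kriging is recovered exactly when no soft data exist.

**Stage 0.** Daily records are averaged to months only when at least 75%
of calendar days have values (the completeness rule used for regulatory
monthly summaries). At PM10-only stations, monthly PM2.5 is first estimated
by hard-data-only estimation (simple kriging) from the PM2.5-observing
stations of the same month so that ratios exist at every station; these
stage-0 values carry an `estimated` provenance flag.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `buffer_rings` | 0–50 … 500–1000 m | emission-transport scales of ring-buffer LUR practice |
| `p_enter`, `p_remove` | 0.05, 0.10 | stepwise thresholds; entry is tested at the *step* level (below) |
| `vif_max` | 10 | conventional multicollinearity cap |
| `n_hard`, `n_soft` | 10, 4 | BME neighborhood caps under the scaled metric `√((h/a_r1)² + (τ/a_t1)²)` |
| `quad_nodes`, `quad_sd_span` | 401, 8 | posterior grid: nodes over conditional mean ± span·SD, extended adaptively if >1e-9 mass reaches an edge |
| `quad_qmc_points` | 512 | Halton points of the rectangle-probability algorithm |
| spatial bin, max τ | 2 km, 12 months | empirical covariance cells, standard variogram practice |

**Stepwise entry calibration.** The entry decision compares the *best*
candidate's partial-F p-value, Šidák-adjusted for the number of candidates
scanned in that step, against `p_enter`. A raw per-candidate threshold
admits at least one pure-noise regressor per step with probability
`1 − (1−p_enter)^m` (≈ 62% for m = 20), which destroys selection validity
exactly in the many-candidate setting ring-buffer LUR creates; the
step-level calibration keeps the per-step false-entry rate at `p_enter`.
Backward removal uses the ordinary per-term p-value against `p_remove`.

**Fitting level.** The ring-buffer features are station-static, so the
pipeline fits the ratio regression on *station-mean* ratios. For static
regressors this gives exactly the coefficients of the pooled monthly OLS,
but with honest degrees of freedom: pooling 36 monthly rows per station
pseudo-replicates every test ~36-fold (months share the station's features
and its temporally correlated residuals), under which stepwise selection
confidently admits spurious granular terms and leave-one-station-out
prediction collapses. `RatioLUR` itself is agnostic — it fits whatever
rows it is given, including monthly rows with time-varying covariates.

**Prediction SD.** `SD(r̂) = √(x'Vx + s²)` includes the residual variance
(a prediction-interval scale, not a confidence-interval scale), because
the soft interval must cover a single month's ratio, not its mean. Under
station-mean fitting, the pipeline widens `s` by the pooled within-station
monthly variance for the same reason.

**Selection power at network scale.** With ~26 spatial units, ~50 ring
candidates and calibrated entry, single-term detection sits near its power
boundary on the default scenario (the stage-0 infill also feeds back
kriging-smoothed, hence biased, ratios at the PM10-only stations — an
intrinsic feature of the design, which treats those estimates as data).
On replicates where no term clears entry the trend reduces to
mean-ratio × PM10; the cross-validated advantage of the two-stage methods
over kriging persists either way, but its landuse component should be
read with this caveat.

## Numerical choices

* **Covariance fitting** minimizes the pair-count-weighted squared error
  over non-missing empirical cells (cells with zero pairs are missing,
  never zero-filled), with bound constraints and ≥5 multi-starts from a
  bound-scaled Latin hypercube (fixed sub-seed). The orderings
  `a_r1 ≤ a_r2`, `a_t1 ≤ a_t2` are enforced by fitting range increments,
  which removes the label-switching ambiguity of the two structures.
* **Rectangle probabilities** (the soft-data mass at each posterior node)
  use the exact normal CDF in one dimension and, in 2–4 dimensions, the
  Genz separation-of-variables transform evaluated on a fixed unscrambled
  Halton set — deterministic, vectorized across all grid nodes, accurate
  to ~1e-4 relative for the well-conditioned low-dimensional rectangles the
  neighborhood cap produces. A soft point whose value is numerically
  determined by the estimation value (a co-located interval) is applied as
  an exact truncation of the grid support instead, so the closed-form
  truncated-Gaussian limit is reproduced to quadrature accuracy.
* **Posterior moments** use composite Simpson quadrature on the normalized
  grid (trapezoid error on the variance would be ~1e-5 at 401 nodes;
  Simpson brings it below 1e-10). Degenerate (zero-width) soft intervals
  are promoted to hard data. Positive-definiteness is guarded by escalating
  diagonal jitter capped at 1e-8 of the zero-lag variance.
* **Ties** in stepwise selection break by smallest p-value then
  lexicographic term name; neighborhood ties break by data index (stable
  sort). All randomized components (field simulation, multi-start
  initialization) are seeded.

## Synthetic cities

Real monthly PM records and cadastral landuse surveys of the kind this
analysis consumes are not redistributable, so the generator builds the
study design synthetically: a 40 × 40 km domain; 18 stations observing
PM2.5 + PM10 and 8 observing PM10 only; 36 months. Landuse is a seeded
patchwork of 250 m cells with basin-city class fractions (road 15%,
residence 20%, forest 22%, industry 5%, park 5%, …). The true ratio
surface is `squash(intercept + Σ coeff · ring feature + smooth spatial
noise)` where `squash` maps the linear predictor smoothly into (0, 1) and
is tangent to the identity at 0.5, so mid-range ratios respond linearly to
the planted coefficients and ordinary least squares recovers them on
noiseless truth. Default planted terms are the four dominant classes at
their reported rings — road, forest, park (500–1000 m) and industry
(300–500 m) — with coefficients on the 1e-7 m⁻² scale typical of ratio
LUR fits; classes whose selected ring is tiny relative to the patch size
are supported but not defaulted, because their features would be nonzero
at only one or two stations of a 26-station network, an extreme-leverage
pattern under which no landuse-based method can predict a withheld station.
PM10 is log-Gaussian (median 50 μg/m³, monthly CV ≈ 30%) with nested
space-time correlation (ranges 11.092/50 km, 3/50 months); PM2.5 is
`ratio × PM10 × exp(residual)` with a nested-covariance log-residual of
~16% local and ~8% regional scatter (same four ranges; sills in the
reported short:long proportion but scaled to log space — concentration-
scale sills of order 10 (μg/m³)² would be physically impossible as
multiplicative factors). Observation noise is additive Gaussian,
SD 1 μg/m³, truncated at zero. The generator reports the fraction of cells
with PM2.5 > PM10 (<5% under defaults).

What the generator does *not* emulate: meteorology-driven dispersion and
advection, calendar seasonality beyond the temporal correlation ranges,
street-network geometry, instrument-specific error structure, and
spatially heterogeneous ratio–landuse relationships. Passing tests
therefore demonstrate correctness and internal consistency of the
estimation machinery under the assumed covariance class and a learnable
ratio surface — not predictive skill on any real city.

## Problem sizes used in the checks

Covariance recovery uses a 30 × 30 site grid over 150 × 150 km observed
100 months, five replicates (the sum-of-two-separable construction makes
the nested model exact to simulate via Kronecker-structured Cholesky
factors). The cross-validation comparison runs the full three-method
leave-one-station-out design on ten default synthetic cities. Both sizes
were chosen so the whole verification cycle runs on a desk machine in
minutes while keeping Monte-Carlo error well inside the stated tolerances.

## Known limitations

* The Gaussian general knowledge base means all soft evidence enters
  through a Gaussian joint; non-Gaussian constraint functions
  (higher-order moments, multiple-point statistics) are out of scope.
* Soft pdfs other than uniform-on-interval are not implemented.
* The spatial covariance is isotropic and stationary; the only
  non-stationarity is the external LUR trend.
* Stage-0 infill kriges within each month independently (temporal
  correlation is not exploited there); its estimates are then treated as
  data when forming ratios, as in the source design, which understates
  ratio uncertainty at PM10-only stations.
* Leave-one-out is at station level by default; the station-month variant
  exists behind `loo_level`, and covariance refitting per fold behind
  `covariance_refit_per_fold` (off: 18 stations make per-fold covariance
  refits unstable).
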