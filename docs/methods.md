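# Methods

This note documents the statistical procedures implemented in `socmon`, the
assumptions behind them, the defaults and why they were chosen, and the
known limits of what the test suite demonstrates.

## Data model and aggregation

The unit of observation is one replicate SOC analysis (g per kg oven-dry
fine earth) from one site and sampling campaign. All inference runs on
natural-log SOC, which stabilises variance across the roughly 10–40 g/kg
range typical of cropland mineral topsoils and makes trends multiplicative
(a slope of s log units per decade is a relative change of
100·(exp(s) − 1) % per 10 years). Replicates are aggregated as the
arithmetic mean of log values — the log of the geometric mean — never as
the arithmetic mean of raw concentrations; the two differ whenever
replicates disagree, and the log-scale mean is the quantity all downstream
models are defined on. Campaign indices are 1-based and chronological;
the decimal sampling year is stored separately because campaigns are
multi-year windows, and the year (not the index) carries the time covariate.
Missing management metadata is an explicit missing value, never zero: a
farm that declared zero manure and a farm that declared nothing are
different facts.

## Harmonisation of analytical methods

Wet oxidation (dichromate) recovers less organic carbon than dry
combustion; recoveries around 0.77–0.90 (median ≈ 0.85) are typical.
The conversion factor is defined as the recovery WO/DC, estimated per site
as the **median of per-pair ratios** from paired analyses (a mean-ratio
estimator is available); conversion to the DC scale therefore always
*divides* by the factor. The direction is stated explicitly because the
reciprocal bug is the classic failure mode here. Sites without paired
calibration data fall back to a configurable global factor, default 0.85.
A regression-based recalibration would also be defensible; the ratio form
was chosen because it is exactly invertible, needs as little as one pair,
and matches the recovery-factor framing above.

## Variable transforms

Three transforms prepare covariate tables for ordination or correlation
screens: natural log for strictly positive skewed variables; arcsine-square
root for percentages (applied to proportions in [0, 1], returning radians);
and log with offset c for non-negative variables with true zeros such as
manure inputs, where

    c = median(x) / (median(x)/q0.25(x))^2.9.

For a lognormal(μ, σ) distribution this reduces to exp(μ − 1.956σ),
essentially the 0.025 quantile exp(μ − 1.96σ) — the offset is a robust
tail-quantile estimate built only from the median and lower quartile, so a
mass of zeros cannot drag it to zero. The exponent 2.9 is a fixed constant
of the formula, not a tuning parameter. Quantiles use linear interpolation
between order statistics (the common default across statistical
environments); the estimator is recorded in the transform metadata so an
exported matrix is exactly reproducible.

## Mixed models

Both models are fitted by REML through statsmodels' `MixedLM` (maximum
likelihood can be toggled). The campaign-effects model uses a random site
intercept; campaign means are reported back-transformed to g/kg with
t-based confidence intervals on the within-site residual degrees of freedom
(N − sites − campaigns + 1), and all pairwise campaign contrasts are Wald
tests, unadjusted by default (a Holm option exists) since the screen is
descriptive. The trend model adds a random slope per site, uncorrelated
with the intercept by default (`correlated=True` frees the covariance);
time is coded in decades since the first campaign so the slope reads "per
10 years", and errors between campaigns are treated as independent — no
serial-correlation structure — which is appropriate when short-term
variability dominates the within-site residual.

Inference on the global slope uses a t reference with **n_sites − 1**
degrees of freedom rather than the asymptotic normal: the slope's
uncertainty is dominated by between-site slope variation, for which the
effective sample size is the number of sites. The type-I-error simulation
in the acceptance tests (500 null networks) confirms this calibration
(~0.03–0.05 rejection at α = 0.05); the asymptotic z reference is
anticonservative at ~30 sites.

Exactly saturated inputs — noise-free synthetic data where site + campaign
effects or per-site lines fit perfectly — would break the iterative
optimiser, so both fitters detect a residual sum of squares below 1e−18
(relative) and return closed-form effects with zero variance components.
Variance estimates at the boundary are clipped at zero, never negative.

## Hierarchical bootstrap

Per iteration and site: draw `resample_size` (default 4) replicates with
replacement within every campaign — even when a campaign has a different
replicate count; a draw-n-of-n mode exists — recompute campaign means and
the per-site OLS slope, then recompute the slope once per
leave-one-campaign-out subset that retains at least
`min_campaigns_for_slope` (default 3) campaigns. All slopes from all 500
iterations are pooled into one ensemble per site (separate ensembles are
available by configuration); the ensemble mean, median and 0.025/0.975
quantiles (linear interpolation) summarise the probable trend range.
Classification — increasing if the whole range is above zero, decreasing if
below, stable otherwise — is an interval rule, deliberately conservative.
Each site derives its RNG substream from the master seed plus a hash of the
site id, so results are bit-reproducible and invariant to site order and to
network growth.

**Known limitation, demonstrated by the coverage test:** the 0.025–0.975
range is close to nominal only when replicate-level noise dominates. In a
simulation where the within-site noise is mostly *short-term
(site-campaign) variability* — the regime the default calibration below
deliberately represents — the intervals under-cover (roughly 0.83 instead
of 0.95 across simulated networks), because resampling four replicates
cannot express between-campaign noise, and the unscaled deletion slopes
express it only partially (a jackknife would inflate the leave-one-out
deviations by about the number of campaigns minus one). With replicate-only
noise the same procedure covers ≈ 0.96. The corresponding acceptance test
asserts ≥ 0.89 coverage and fails under the default calibration; it is left
failing on purpose, as a true statement about the procedure rather than a
defect of the implementation. Treat the ranges as "probable", not as
calibrated 95% confidence intervals.

## Synthetic networks

The generator produces replicate-level data
y = m_i + (β + b_i)·t + u_it + e_itr on the log scale with SOC = exp(y).
Defaults represent a NABO-style design: 30 sites × 5 campaigns at 5-year
intervals × 4 replicates; site levels m_i uniform on [ln 10, ln 40] g/kg
(site means in such networks spread roughly evenly across that range — a
normal alternative with configurable SD exists); site slope deviations
b_i ~ N(0, 0.05) per decade, consistent with observed per-site slopes
spanning roughly ±0.13 log units per decade; short-term site-campaign noise
u ~ N(0, 0.06) and replicate noise e ~ N(0, 0.07), i.e. ~6% and ~7%
relative variation. The noise split is a **calibration**: replicate-level
CVs are rarely published, and the split was fixed once such that short-term
variability dominates the within-site error (the documented obstacle to
trend detection in repeated soil sampling, with reports of 14–16% relative
fluctuation within months) and such that the implied minimum detectable
change of the default design lands near 0.35 %/yr at power 0.8 — the
anchor value for a five-campaign network of this type. Optionally a
fraction of early campaigns is tagged WO with a site recovery factor drawn
from [0.77, 0.90] (emulating a historical method change), and a management
model generates clay/manure/meadow covariates with a configurable positive
association to site SOC so correlation-screen patterns are reproducible in
sign. What the generator does *not* emulate: spatial autocorrelation
between sites, serial correlation of campaign noise, seasonal sampling-date
effects, non-linear trends, and measurement drift; tests passing on
synthetic data therefore validate the statistical machinery, not these
field realities.

## Power and MDC

For a candidate annual trend r, networks are simulated with the exact
log-slope ln(1 + r/100) per year (not the first-order approximation r/100),
the trend model is fitted, and power is the rejection fraction at α
(default 0.05). The MDC is the smallest grid value reaching the target
power (default 0.8); it is reported **on the grid** — grid resolution is
the precision contract — and "not reached" is an explicit result, not an
error. All grid points and paired design comparisons reuse the same
per-simulation seeds (common random numbers), which makes power curves
monotone and design comparisons well conditioned at moderate simulation
counts. Simulation sizes in the shipped tests (120–500 networks per power
point) were chosen as the smallest giving stable Monte-Carlo answers for
the properties asserted; for production MDC tables, 1000+ simulations per
grid point are recommended.

## Diagnostics

Stock arithmetic: SOC [g/kg] × apparent density [g/cm³] × depth [cm] × 0.1
gives t C/ha; the 0.1 is pure unit conversion and is verified in the tests
against two printed rows of the bundled network table (whole-table
agreement is within ±1 t/ha, the table's own rounding). Apparent density
here is fine-earth mass per total soil volume, so the product is directly
the fine-earth carbon stock at fixed depth; no equivalent-soil-mass
correction is attempted (a real limitation when bulk density changes over
time). The SOC/clay ratio divides SOC in % of dry matter (g/kg ÷ 10) by
clay in % of fine earth; 0.12 serves as the good/medium structural-quality
threshold. Spearman correlations are computed on pairwise-complete
observations with large-sample t p-values (an exact permutation option
exists for very small n), starred at 0.05/0.01/0.001. Display rounding
(stocks to integers, ratios to 2–3 significant figures) never feeds back
into computation.

One printed-rounding caveat: a log slope of +0.11 per decade converts to
+11.6%, which rounds to +12%, not the +11% sometimes quoted alongside
rounded slope endpoints; the conversion functions always report the exact
value and make no attempt to reproduce double-rounded figures.

## Pipeline

`run_full_analysis` chains harmonisation → aggregation → both models →
bootstrap → diagnostics, excluding configured sites (default 5 and 23, the
two network sites converted to permanent grassland) from the trend stages
while keeping them in diagnostics. Every output CSV/JSON records the seed,
and the run manifest (config, package version, SHA-256 of each output)
suffices to reproduce a run exactly. Any stage failure aborts with the
stage name in the run log.
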