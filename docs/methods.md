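# Methods

## The experimental structure being emulated

The synthetic-data generator (`leafsi.synthetic`) produces a multi-site
grassland fertilization × grazer-exclusion experiment: `n_sites` sites
(default 17) spanning mean annual precipitation 365–1898 mm/yr and mean
annual temperature 0.3–22.1 °C, each with 2–5 blocks, each block holding
one plot per cell of the 2×2 NPK×FENCE factorial, and one grass composite
sample per plot. Site covariates (MAP, MAT, PET, soil N, soil C, pH, sand,
organic matter, a 0–29 grazing index) are drawn with loose, realistic
couplings (PET rises with MAT; soil C tracks soil N with substantial C:N
scatter; OM tracks soil C).

Leaf Si is generated on the natural-log scale:

```
log Si = mu0 − drop·[soilN_plot > thr] + a_site·atten + beta_npk·atten·NPK
         + beta_fence·FENCE + slope(MAP)·(C − c_mid) + eps·atten
```

with `a_site ~ N(0, site_sd)`, `eps ~ N(0, resid_sd)` and
`slope(MAP) = slope_intercept + slope_per_map·MAP`. Any fixed log base
would be equivalent up to scaling; natural log is used and adjusted means
are back-transformed by plain exponentiation (no bias correction).

Key default parameters, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `mu0` | log 1.72 | control-plot median Si, % dry weight |
| `beta_npk` | −0.49 | fertilization effect on log Si |
| `site_sd` / `resid_sd` | 0.35 / 0.35 | between-site and within-site SD of log Si |
| `slope_intercept`, `slope_per_map` | −0.152, 8e−5 | within-site log-Si~C slope: strongly negative at 365 mm, ≈0 at 1900 mm |
| `soil_n_threshold` | 0.43 %N | local soil N above which Si variation collapses |
| `attenuation` | 0.2 | factor applied to `beta_npk`, the site intercept and `resid_sd` above the threshold |
| `threshold_baseline_drop` | 0.9 | baseline log-Si drop above the threshold (high-soil-N plots behave like fertilized ones, so Si is uniformly low there) |
| `soil_n_plot_sd` | 0.06 %N | within-site, plot-scale soil N heterogeneity (~15 % CV, typical of field-scale soil variability) |
| `c_range` | 38–48 % | leaf C, uniform per sample |
| `element_bases` | N 1.5, P 0.2, K 1.8, Ca 0.6, Mg 0.25 % | macronutrient baselines |

The soil-N threshold acts on *plot-level* soil N: each plot's measured
soil N scatters around its site mean, and the attenuation follows the
local value. This matches designs in which soils are sampled per plot and
means the threshold location is identified by the data at the plot scale;
with a purely site-level mechanism and 17 sites it would only be
identified up to the spacing of adjacent site means (~±0.05 %N).

Macronutrients follow pure compositional closure: element = baseline ×
(100 − C)/(100 − c_mid) × exp(N(0, 0.2)). Closure of the whole composition
(sum < 100 % dry weight) is enforced by rejection sampling on the same
random stream, so output is seed-stable. The generator does **not**
emulate: species composition, spatial structure within blocks, temporal
variation, element covariances beyond closure, or measurement error in
leaf chemistry. Passing tests therefore demonstrate correctness of the
estimators under the assumed generating process, not robustness to those
real-data features.

## Mixed models

`leafsi.lmm` fits the random-intercept model by profiling the variance
ratio λ = σ²_site/σ²_resid: for fixed λ the GLS coefficients and σ²_resid
have closed forms (compound-symmetric blocks), leaving a one-dimensional
optimization over log λ (coarse grid then Brent, with the λ = 0 boundary
checked explicitly). The restricted likelihood retains all constant terms
and matches lme4/statsmodels conventions; a test cross-checks coefficients,
variance components and log-likelihood against statsmodels' `MixedLM`, and
an independent dense-matrix grid-search oracle verifies the optimum to
1e−4 log-likelihood units.

Conventions:

- AIC is always computed from the ML likelihood (candidate models differ
  in fixed effects), with df = intercept + fixed terms + 2 variance
  parameters, even when coefficients are reported from REML.
- σ²_f for R² is the variance (ddof = 1) of the fixed-effect linear
  predictor over the observed design.
- t-statistics use residual df = n − p; this df choice is approximate and
  documented as such.
- Adjusted means are population-level predictions (random effects at
  zero) with other terms at their observed averages; on the log scale the
  mean ± SE maps to the % scale by exponentiation (delta method for SE).

Diagnostics: the Anderson–Darling normality statistic uses the
estimated-parameters correction `A* = A(1 + 0.75/n + 2.25/n²)` with the
standard piecewise p-value approximation (scipy exposes only critical
values); the non-constant-variance check is the score test that regresses
squared standardized residuals on fitted values (half the regression sum
of squares ~ χ²₁), the same construction as the classic `ncvTest`.

## Model selection

All subsets of the main effects, plus whitelisted two-way interactions
whenever both parents are present; the null model is always included.
Ties in AIC break toward fewer parameters, then the formula label.
ΔAIC < 2 flags equivalence, ΔAIC > 7 poor fit. Akaike weights are
normalized over exactly the set passed in — computing weights over a
pruned display subset gives different (larger) values than over the full
candidate set, so the caller controls which is meant.

## Regression trees

CART for a continuous response, written in-package: greedy binary splits
minimizing pooled SSE, thresholds at midpoints of adjacent sorted values,
ties toward the lowest-index variable then the smallest threshold; a split
must reduce relative error (scaled by root SSE) by at least `cp_min`
(default 0.01) with `min_leaf` (default 7) per child. Pruning follows the
weakest-link cost-complexity sequence; k-fold CV (default 10, folds
stratified by site through seeded within-site shuffling) scores each
complexity at the geometric means of consecutive sequence values, each
fold rescaling complexity by its own root SSE. The CV-error SE is
estimated from the spread of fold totals (sd of fold errors scaled to the
full-data level divided by √k) — simpler than the per-observation
delta-method formula used elsewhere, with identical one-SE-rule semantics:
select the largest complexity whose CV error is within one SE of the
minimum.

## Dilution null model

For focal element F, each replicate builds a response by picking,
independently per sample, one of the five nonfocal elements uniformly at
random and taking that sample's concentration; the same random-intercept
model of response on %C is refit and the %C slope recorded (R = 999 by
default; empirical p-values use the add-one correction
`p = (1 + #{null ≤ obs})/(R + 1)`, both tails reported). Since the fixed
design (intercept, %C) is constant across replicates, all replicate fits
are evaluated together on a dense grid of the variance ratio (160
log-spaced points plus the zero boundary); the discretization error in the
slope is orders of magnitude below Monte-Carlo noise (verified against the
exact per-replicate fit).

A structural caveat, documented deliberately: the null mixes the raw
concentrations of the nonfocal elements, so its center is the slope of the
*average* nonfocal element. For a focal element whose typical concentration
is well above that average, the observed slope is proportionally steeper
than the null center even under pure closure — the test is conservative for
rare elements and anti-conservative for abundant ones. Its Type-I error is
therefore calibrated under exchangeable conditions (equal element
baselines), which is how the calibration scenario is defined; applied to
strongly unequal concentrations the lower-tail p-value for abundant
elements should be read with this offset in mind. The slope is fitted on
raw % concentrations by default (a `log_response` flag is provided).

## Per-site slopes and the precipitation gradient

Stage one: OLS slope of %Si on %C within each site (raw percent scale;
all plots by default, `controls_only` optional); sites with fewer than 3
samples or constant C are skipped with a warning. Stage two: OLS of the
site slopes on MAP (or MAT/PET via the `covariate` argument). First-stage
estimation error is ignored by default, matching the conventional
two-stage reading of such analyses; an inverse-variance weighted mode is
provided as an extension and reduces to OLS for equal SEs.

## Chemometrics

Kennard–Stone selection runs on mean-centered spectra with Euclidean
distances; ties break toward the lowest sample index (published
implementations differ here, so the rule is documented). PLS1 is fit via
scikit-learn's NIPALS `PLSRegression` (no scaling beyond centering; no
SNV/derivative preprocessing), with the component count chosen by holdout
R² up to a cap of 10. External validation R² is the squared Pearson
correlation between predicted and reference values (a 1 − SSE/SST
definition is available by flag). Synthetic spectra are Beer–Lambert
mixtures of three Gaussian-band constituents; the reference-value
measurement noise (SD 0.25 %dw) is set so the full pipeline's
external-validation R² centers on 0.83, emulating a realistic NIRS
silicon calibration.

## Pipeline and seeding

`leafsi.pipeline.run` executes generate → diagnostics → two-way model →
model selection → tree → dilution → slopes → chemometric calibration,
writing per-stage CSV/JSON, a manifest (config, package version, and every
seed actually consumed) and a text summary. Seeds are hierarchical: each
stage's substream is derived from the master seed and a hash of the stage
name, so adding or removing stages never perturbs another stage's results;
reruns with the same config are bit-identical (CSV floats are written with
`repr`, which round-trips exactly).

## Validation-study conditions and problem sizes

The canonical scenarios live in `leafsi.scenarios` and are shared by the
test suite and `scripts/acceptance.py`:

- **NPK-effect recovery**: β_NPK = −0.49, residual SD 0.60 (chosen so the
  two-way model's coefficient SE is ≈0.11), soil N below the threshold and
  Si~C coupling off so "noise" maps cleanly onto the SE; 200 replicates in
  the test, 100 in the script.
- **Adjusted-means recovery**: control/fertilized means 1.72/1.27 %dw;
  100 replicates; the replicate-averaged estimates must sit within 2
  average SEs of the truths.
- **Threshold recovery**: generator defaults; 100 replicates; the pruned
  tree's first split must be on soil N within ±0.05 of 0.43 %N in ≥80 %.
- **Dilution calibration / power**: exchangeable (equal-baseline)
  elements with the closure slope, or with an injected Si–C trade-off
  (−0.12 per %C on the log scale); 200/100 replicates at R = 199 (p-value
  resolution 1/200) for the rate estimates and a single R = 999 run for
  the Monte-Carlo-mean oracle check.
- **Aridity gradient**: slope −0.16 per %C at 365 mm rising to ≈0 at
  1900 mm, residual SD 0.25; 100 replicates; the second-stage coefficient
  must be positive and significant in ≥80 %.
- **Chemometrics**: 1725 synthetic spectra, 20 % Kennard–Stone
  calibration fraction; external-validation R² within ±0.05 of 0.83.

## Known limitations

- Single random intercept only: no nested/crossed random effects or
  random slopes; no REML-based model comparison.
- The dilution null's magnitude sensitivity (above) is inherent to the
  procedure as specified; a log-ratio compositional analysis would avoid
  it but is intentionally out of scope.
- Second-stage slope inference ignores first-stage estimation error
  unless the weighted mode is enabled.
- The AD p-value approximation is accurate to ~1e−3 in the tails, which is
  ample for the diagnostic's purpose.
- Tree building assumes complete numeric predictors (no surrogate splits
  or missing-value handling).
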