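# Methods

## Cohort generator

The generator draws, in a fixed stream order (sex, then the bivariate
height/log-weight sample), from

* (H, log W) ~ N((160.6 cm, 4.2 log kg), Σ), SD(H) = 6.2, SD(log W) = 0.19,
  Cov(H, log W) = 0.59 cm·log(kg) — female US-adult anthropometrics;
* sex ~ Bernoulli(0.5); males get +13 cm and +9.4 kg added on the
  natural scales after the log-weight is exponentiated;
* outlier removal last: weight above 180 kg or below 38 kg, height
  below 145 cm. Rows are dropped, not resampled, so the realized cohort
  is slightly smaller than `n_population`.

The headline "0.59 (co)variance" is ambiguous between a covariance and
a correlation. We take it literally as a covariance (implied
correlation ≈ 0.50); `cov_is_correlation=True` selects the other
reading. Eligibility is inclusive, BMI ≥ 35. Ideal weight is the weight
at BMI 25 for the subject's height; excess weight is weight minus ideal
weight.

Truncation matters for parameter recovery: dropping heights below
145 cm (≈ 2.5 SD) raises the female mean height of the *surviving*
cohort by ≈ 0.10 cm. Recovery of the generative parameters is therefore
assessed on the pre-filter draw (`simulate_population(...,
apply_filters=False)`).

## Weight loss and its genomic prediction

Both variables use the same standardize–mix–rescale recipe: standardize
the driver, mix with an independent standard-normal residual, then
affinely rescale the mixture to the target mean and SD (which pins the
sample moments exactly and leaves sample correlations untouched).

* PEWL: driver = baseline weight, mixing coefficient
  `sign × 0.59`, residual coefficient √(1 − 0.59²) ≈ 0.807, rescaled to
  63 ± 23 %. Two deliberate choices:
  * **Sign.** The construction is stated unsigned in the source
    material, but the downstream narrative (adverse-event risk falling
    as the threshold rises) requires that better responders weigh
    *less* at baseline, so the default sign is negative;
    `pewl_weight_assoc_sign=+1` restores the literal construction.
  * **Residual coefficient.** A fixed 0.85 residual coefficient yields
    correlation 0.59/√(0.59² + 0.85²) ≈ 0.570, not 0.59. The default
    (`pewl_residual_mode="exact"`) uses √(1 − a²) so the configured
    association is the actual target; `"literal"` keeps the 0.85 mix.
* Predictor: driver = actual PEWL, correlation 0.316 (predictive
  R² = 0.1; an abstract-level figure of R² = 0.07 circulates for the
  same design — 0.316 is the operational value), rescaled to 63 ± 7.6 %.
  Correlations up to |r| = 1 are accepted; r = 1 reduces to an exact
  affine rescaling.

PEWL is not truncated to [0, 100]: the normal tails are kept, so a few
subjects gain weight or overshoot the ideal BMI. Post-surgery weight is
`weight − excess_weight × PEWL/100`.

## Risk models

**BMI → lifetime T2DM probability.** Two monotone strategies:

* `anchored_spline` (default): a monotone PCHIP interpolant through
  (BMI, lifetime-risk) anchors at BMI-category midpoints —
  (17, 0.10), (21.75, 0.185), (27.5, 0.325), (32.5, 0.56), (42.5, 0.72) —
  sex-averaged adult lifetime risks from the published dose-response
  literature, extended monotonically to (55, 0.78) to cover the
  reference range.
* `ecdf`: standardize a dense uniform grid of 2001 BMIs over the
  reference range [20, 55], multiply by 0.8, and read probabilities off
  the empirical CDF of the scaled grid. The ECDF convention is
  rank/(n−1) (strict counting), so the reference endpoints map to
  exactly 0 and 1. Because the ECDF of a monotone transform of a
  uniform grid is the uniform CDF, this strategy is a linear ramp and
  the 0.8 scale has no effect; it is retained as the literal historical
  construction.

Either map evaluated naively over the eligible (BMI ≥ 35) cohort gives
a mean untreated risk far above the documented 0.28 — the upper tail of
any monotone map normalized over [20, 55] sits near its top. A
**calibration step** therefore shifts the map by a single additive
constant on the log-odds scale, found by Brent root-finding
(xtol 1e-9, bracket ±40), so the eligible-cohort untreated mean equals
the 0.28 target. The shift preserves monotonicity and the [0, 1] range;
calibration of an already-calibrated map is a fixed point (the scalar
moves by < 1e-6). BMI outside [20, 55] clamps to the boundary value:
lifetime-risk estimates outside the reference range are unsupported, so
we do not extrapolate. Probabilities are clipped to [1e-12, 1 − 1e-12]
before the logit.

**Adverse events.** The published AE risk function is not available in
enough detail to transcribe, so the model is our own construction
consistent with its qualitative behavior: logistic in the standardized
baseline covariate (weight by default, BMI via `ae_covariate="bmi"`)
plus a male indicator, slope 0.5 per SD and 0.3 log-odds for males,
intercept calibrated by Brent root-finding so the eligible-cohort mean
is 0.049. AEs only occur with surgery; untreated AE risk is zero.

## Decision analysis

* **Population case probability**, per threshold τ: the unweighted
  average of the treated-group mean and the untreated-group mean,
  transcribing the printed formula — *not* the population-size-weighted
  mean (`eq1_weighted=True` gives the weighted variant). Subjects with
  αᵢ exactly equal to τ count as untreated (measure-zero for a
  continuous predictor). If one group is empty, the other group's mean
  is returned unhalved; halving would create a spurious discontinuity.
* **Allocation**: candidates are subjects with αᵢ > τ (strict), ranked
  by αᵢ descending, ties broken by ascending subject id, truncated to
  the surgical capacity (1000 = $20M at $20k per procedure). For τ
  below roughly the 1000th-largest prediction the treated set is the
  fixed top-1000, so sweep curves are flat there.
* **Cases prevented** N|τ = S·(baseline − mean treated-set risk), with
  two comparators kept side by side because the source formula and its
  surrounding text disagree: `random_allocation` (default; baseline =
  mean treated-risk over the whole eligible cohort, i.e. the same S
  surgeries spent first come, first serve — the comparator under which
  the ~41-cases-at-τ=80 figure is reproduced) and `untreated_baseline`
  (baseline = mean untreated risk; counts the benefit of surgery itself
  plus selection, and is negative for AEs since surgery causes them).
  Thresholds where nobody is allocated carry NaN in the sweep table.
* **Conditional risk curves** (individual decision support): each
  per-subject risk is regressed on the predictor with a cubic B-spline
  basis (interior knots at quantiles), degrees of freedom chosen from
  {4…8} by generalized cross-validation, evaluated on a grid inside the
  observed predictor range (no extrapolation) and clipped to [0, 1].

## Randomness and determinism

One master seed; per-stage substreams (population, PEWL residuals,
predictor residuals) are spawned from its `SeedSequence` in a fixed
order, so stage-level reruns reproduce full-pipeline runs and a
(config, seed) pair determines every output file bit-for-bit.

## What the generator does and does not emulate

It reproduces the marginal and joint distributions the study conditions
state: anthropometrics with a height-weight correlation, a realistic
weight-loss distribution tied negatively to baseline weight, and a
predictor with modest accuracy. It has no age structure, ethnicity,
comorbidity, time-to-event dimension ("lifetime risk" is one static
probability), measurement error, or real genotypes — the predictor is a
statistical surrogate defined by its accuracy. Passing tests therefore
demonstrate internal consistency of the decision analysis under these
idealized conditions, not performance on real registry data.

## Problem sizes and tolerances

All simulations run at the full stated size (150,000 subjects,
~3,600 eligible); five replicate seeds are averaged wherever a quantity
is checked against its target, since single-seed tail quantities (the
τ = 80 treated set holds only ~45–60 subjects, giving a between-seed SD
of ≈ 6 prevented cases) are noisy. Monte Carlo checks use 4-standard-
error bands at the realized n; calibrated means are checked to 1e-3,
the calibration's own tolerance is 1e-9.

## Known limitations

* The two calibration targets (0.28, 0.049) are enforced exactly by
  construction, so they validate the calibration plumbing, not the risk
  maps' shapes; the cases-prevented quantities *do* depend on the shape
  and differ by a few cases between the `anchored_spline` and `ecdf`
  strategies.
* The printed population case probability (unweighted mean of group
  means) is not a population mean when group sizes differ; both
  variants are provided but the unweighted form is the default for
  fidelity.
* The AE model's slope coefficients are conventions, not estimates;
  only their signs and the calibrated mean are substantive.
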