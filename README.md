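# pewlsim

Monte Carlo simulation of the clinical utility of a genomic predictor of
bariatric-surgery weight loss under resource-constrained allocation.

## The problem

Whole-genome prediction of treatment response is usually modest: a
predictor of percentage excess weight loss (PEWL) after gastric bypass
with predictive R² ≈ 0.1 explains little variance at the individual
level. But when surgical capacity is finite — say 1000 procedures for
thousands of eligible patients — even a weak predictor can be used to
*rank* candidates, and ranking is enough to shift population-level
outcomes. `pewlsim` quantifies that effect for two outcomes: lifetime
Type-2-diabetes (T2DM) risk, which surgery lowers by lowering BMI, and
surgical adverse events (AE), whose risk rises with baseline body
weight. It is aimed at biostatisticians and methodologists studying the
clinical utility of polygenic prediction and decision-threshold
analysis.

## The model

1. **Cohort.** Heights and log-weights of 150,000 adults are drawn from
   a bivariate normal, (H, log W) ~ N((160.6, 4.2), Σ) with
   SD(H) = 6.2 cm, SD(log W) = 0.19, Cov = 0.59; sex is a fair coin and
   males receive +13 cm and +9.4 kg. Outliers (W > 180 kg, W < 38 kg,
   H < 145 cm) are removed. Subjects with BMI ≥ 35 are surgery-eligible
   (≈ 2.4%, ~3,600 subjects). Ideal weight is the weight at BMI 25;
   excess weight is the difference.
2. **Outcomes.** Actual PEWL ~ N(63, 23²) with correlation −0.59 to
   baseline weight; the genomic prediction αᵢ ~ N(63, 7.6²) with
   corr(α, PEWL) = 0.316. Post-surgery weight is
   W − excess · PEWL/100.
3. **Risks.** A monotone map sends BMI to lifetime T2DM probability
   (evaluated at baseline BMI if untreated, post-surgery BMI if
   treated), calibrated so the eligible-cohort untreated mean is 0.28.
   AE probability is logistic in standardized baseline weight and sex,
   calibrated to an eligible-cohort mean of 0.049.
4. **Decision analysis.** For each threshold τ ∈ {55, …, 80}, subjects
   with αᵢ > τ (top-ranked, capped at 1000) are allocated surgery. The
   population case probability is
   P(C)|τ = ½ [ mean_{αᵢ>τ} P(Cᵢₜ) + mean_{αᵢ≤τ} P(Cᵢᵤ) ],
   and the additional cases prevented by using the test is
   N|τ = 1000 · [ mean P(Cᵢ·) − mean_{treated} P(Cᵢₜ) ],
   where the baseline mean is over treated risks (first-come-first-serve
   comparator) or untreated risks (no-treatment comparator).

## Worked example

```bash
pewlsim run --out demo --seed 42
```

prints

```
eligible=3520 mean_ae=0.0490 mean_t2dm_untreated=0.2800 prevented_t2dm_at_tau_max=49.2
```

i.e. 3,520 of 150,000 simulated subjects were eligible; the calibrated
mean AE probability is 0.049 and the mean untreated lifetime T2DM risk
is 0.28; selecting the patients predicted to lose more than 80% of
their excess weight prevents ≈ 49 additional T2DM cases (this tail
quantity varies by several cases between seeds) compared with spending
the same 1000 surgeries first come, first serve. The output directory
contains the cohort, outcome, risk, threshold-sweep and decision-curve
CSVs, a manifest, and a figure of prevented T2DM and AE cases versus τ.
Slicing the sweep table for this run:

```
 tau  n_treated  n_prevented_t2dm_random_allocation  n_prevented_ae_random_allocation
55.0       1000                           21.275332                          7.611484
65.0       1000                           21.275332                          7.611484
75.0        219                           38.707941                         11.572109
80.0         57                           49.155614                         16.383469
```

Raising τ shrinks the treated set onto the best predicted responders:
prevented T2DM cases rise, and prevented AE cases rise too because high
predicted weight loss correlates with lower baseline weight and hence
lower surgical risk. A library-level API mirrors each stage
(`simulate_population`, `simulate_pewl`, `simulate_predictor`,
`build_risk_profiles`, `threshold_sweep`, `conditional_risk_curves`);
see the module docstrings.

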