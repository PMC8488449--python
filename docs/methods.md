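# Methods

## Causal structure and estimands

The analysis targets the effect of maternal education (3-level exposure *A*,
disadvantage-coded high = 0, mid = 1, low = 2) on childhood obesity at 6–7
years (*Y*), with daily energy intake at age 3 (*M*, kcal/day) as the mediator
of interest. Child ethnicity (*C*) is the baseline confounder; standardized
birthweight category, general health, moderate activity and TV time are
intermediate confounders (*L*) — caused by the exposure, and potentially
causing both the mediator and the outcome. The assumed ordering is

    C → A → L → M → Y,   with C → Y and a direct A → Y path.

The **controlled direct effect (CDE)** reported here is the effect of *A* on
*Y* with *M* held at each child's observed value. It is estimated with a
logistic marginal structural model: a weighted logistic regression of *Y* on
*A* and *M*, where the weights remove confounding of *A* by *C* and of *M* by
(*C*, *L*, *A*). Note that any *A → L → Y* pathway is *part of* the CDE —
fixing *M* does not block it — so when the generator includes
education→confounder links, the marginal education coefficient legitimately
exceeds the direct logit coefficient. The recovery benchmarks therefore use a
configuration with those links switched off (`recovery_benchmark_params`),
where the two coincide.

## Weights

* Exposure: stabilized weight `P(A = aᵢ) / P(A = aᵢ | Cᵢ)`; the denominator
  is a 3-category multinomial logistic model of education on ethnicity, the
  numerator the marginal education distribution. Stabilization keeps the
  weights centred on 1 and bounds their variance; the package asserts
  mean ≈ 1 (±0.05 at n = 20 000) as a specification diagnostic.
* Mediator: stabilized density ratio `f(Mᵢ | Aᵢ) / f(Mᵢ | Aᵢ, Cᵢ, Lᵢ)` with
  both densities normal on the log-kcal scale, estimated by two linear
  regressions of log intake with maximum-likelihood residual variances.
  Intake is strongly sex-patterned, so sex enters both regressions by default
  (`include_sex=True`); because it appears in numerator and denominator it
  does not de-stabilize the weight.
* The combined weight is the elementwise product, truncated at the empirical
  1st and 99th percentiles of the combined-weight distribution (percentiles,
  not absolute values 0.01/0.99 — absolute truncation at 0.99 would destroy
  weights centred at 1).

## Confidence intervals

Risk ratio (RR = p̂(low)/p̂(high)) and risk difference (RD, percentage
points) are computed from a companion fit with education as a continuous
linear term, predicting every child at codes 2 and 0 and averaging
(g-computation over the sample). Two CI methods are provided:

* **bootstrap** (default of `inequality_metrics`, 499 replicates):
  nonparametric resampling of children with the weights re-estimated inside
  every replicate; percentile intervals. This propagates weight-estimation
  uncertainty.
* **delta**: sandwich-covariance propagation through the g-computation map
  (log scale for RR). It ignores weight-estimation noise and is the default
  in the pipeline and in replicated simulation loops, where a bootstrap per
  replicate would be prohibitively slow. In the null-calibration benchmark
  the delta intervals cover RR = 1 in ≈98% of replicates, i.e. slightly
  conservative, which is acceptable for a calibration check asserting ≥90%.

The weighted logistic fits use IRLS (statsmodels GLM, deviance tolerance
1e-8, 100 iterations max) with HC1 robust covariance; non-convergence and
suspected separation (|coefficient| > 30) raise errors rather than returning
garbage.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which everything else is validated.

* **Marginals** are calibrated to the published imputed-sample column of the
  survey the package emulates: 51.3% boys; education split 9.4/66.4/24.2
  (low/mid/high); 96.1% white; confounder category shares (e.g. birthweight
  13.1/72.8/14.1); 6.7% obesity at age 3; 8.3% at 6–7 years.
* **Intake** is log-normal — dietary energy is right-skewed — with
  sex-specific log-medians fixed at 1311.5 (boys) and 1273.5 kcal (girls).
  The source statistics include no dispersion, so `log_sd = 0.24` is a
  calibration choice, selected once so the proportions at or below the EAR
  (≈32% boys, ≈24% girls) approximate the published 33.5%/22.0%. The default
  education effect on intake is zero (no education–intake association was
  observed in the data being emulated); confounder effects on intake default
  to zero and are switched on explicitly in benchmarks that need mediator
  confounding.
* **Obesity** at each age is drawn Bernoulli from a logistic model, and the
  BMI z-score is then drawn from the standard-normal tail consistent with the
  flag and the 95th-centile cut-off (1.6449). Thresholding a Gaussian z-score
  instead would make the true binary model probit, and the logit coefficients
  the MSM estimates would not correspond to any generator parameter; the
  chosen construction keeps the z/flag pair internally consistent *and* the
  binary outcome exactly logit-linear, so recovery tests have a well-defined
  truth. The z-scores are consequently a consistency device, not a realistic
  continuous BMI distribution.
* **Intercepts** of the two obesity models were calibrated by root-finding on
  the simulated marginal expectation (n = 2 000 000) to hit 6.7% and 8.3%,
  and frozen as defaults (−3.0203 and −2.9298).
* **Outcome coefficients** default to 0.39 per disadvantage level and 0.10
  per 100 kcal — sized so the unadjusted low/high risk ratio is near 2 and a
  13% universal intake reduction produces a ~1 percentage-point prevalence
  drop, the qualitative behaviour of the emulated analysis.
* **IMD** is a standard-normal score with theoretical quintile cuts,
  independent of the other variables; it is a targeting variable only.
* **Missingness** supports MCAR and MAR-on-education (per-column probability
  times an education-specific factor); exposure and outcome are never masked,
  matching the analytic-sample restriction the emulated analysis used. MNAR
  is out of scope (the analysis assumes MAR).

What passing tests on this generator do *not* show: robustness to mediator
density misspecification (real intake is not exactly log-normal), to
measurement error in 2-day food diaries, to exposure misclassification, or to
informative attrition. The generator has no education→IMD link and no
prior-obesity→outcome tracking beyond shared causes, both of which real
cohorts exhibit.

## Interventions

Scenarios are declarative (`ScenarioSpec`): an eligibility rule (all;
IMD score ≥ mean + 1 SD; obese at 3y; intake above the sex EAR), a reduction
rule (shift by the sex-specific median−EAR gap; a fixed percentage; truncate
to the EAR), an uptake probability applied as independent Bernoulli draws,
normal variability around the adjusted level, and a lower bound.

* The sex-specific shift arithmetic: boys 1311.5 − 1171.0 = 140.5 kcal
  (10.7%), girls 1273.5 − 1076.0 = 197.5 kcal (15.5%), overall 13.0% at
  51.3% boys.
* Variability default: SD = 25% of the mean absolute reduction among treated
  children (per sex for the shift rule), re-centred so the mean treated shift
  equals the target; zero for the truncation rule, where jitter would defeat
  the cap. The magnitude of the "normal distribution around the adjusted
  level" is not specified by the design being emulated, so this is a
  documented, configurable default.
* The floor is mean − 2 SD of *observed* intake, computed before any
  intervention; a child never moves below it, a child already below it is
  untouched, and no child's intake ever increases.
* Uptake is a per-child Bernoulli draw (seeded), not a deterministic scaling
  of effects by the uptake fraction — the individual-level interpretation of
  "75% of eligible children comply".
* The intensive 21.3% reduction is taken as a fixed constant; its derivation
  from adult energy requirements is not reproduced.
* Impacts are g-computed: per-child probabilities are re-predicted from the
  already-fitted CDE model with modified intake and averaged. The model is
  not refitted — the counterfactual changes the mediator distribution, not
  the outcome mechanism.

## Multiple imputation

`chained_imputation` is a lightweight MICE: per incomplete column, a
conditional model (linear regression on log intake / z-scores / IMD score;
multinomial logistic for categoricals) fitted on a bootstrap resample of the
observed rows — the bootstrap supplies the parameter draw that makes the
imputation "proper" — followed by a parametric draw from the predictive
distribution. Ten cycles by default, distinct sub-seeds per imputation,
m up to 50 supported. Predictive mean matching is deliberately not used
(parametric draws are simpler and adequate for the simulation role the
imputer plays here). Derived columns stay coherent: an imputed BMI z-score at
age 3 is redrawn from the correct tail when an observed obesity flag
contradicts it, and missing flags/quintiles are derived from their parents.
Rubin's rules pool estimates (total variance W̄ + (1 + 1/m)B, t-based CI with
Rubin df); m = 1 degenerates to the within-imputation variance with a
warning.

## Growth reference

BMI z-scores use the LMS method, `z = ((X/M)^L − 1)/(L·S)` (log form at
L = 0), linearly interpolating L, M, S in age within sex. The bundled
reference table is **synthetic** (ages 2–8, both sexes, monotone M): the real
UK90 coefficients are licensed and nothing downstream depends on their exact
values — cohort z-scores come from the generator, and the reference is used
for classification logic and round-trip tests. Centile cut-offs are applied
on the z-scale as standard-normal quantiles (overweight > 1.0364, obese
> 1.6449), strictly "greater than". EARs are constants (1171.0 / 1076.0
kcal/day at age 3); their BMR × PAL derivation is out of scope.

## Pipeline determinism and problem sizes

A master seed spawns a fixed table of per-stage `SeedSequence` children
(generate, missingness, imputation, bootstrap, scenarios), so adding a stage
never perturbs earlier streams and identical configs produce byte-identical
reports. Report percentages are printed to 1 decimal place.

Benchmark sizes, chosen to keep Monte-Carlo error well inside the asserted
tolerances: coefficient recovery uses 10 replicates of n = 20 000 (bias
tolerance 0.05 on the logit scale; observed ≈0.01); null calibration uses
200 replicates of n = 5 000 (coverage ≥ 90%; observed ≈98%); weight and
uptake diagnostics use single cohorts of n = 20 000; generator prevalence
calibration uses n = 50 000 (tolerance 0.7 pp around 8.3%).

## Known limitations

* Absolute prevalences, RRs and RDs of the emulated survey are not
  reproducible — they require the original microdata; the package reproduces
  the analysis machinery, the published arithmetic, and the table *shape*.
* The delta-method CIs understate uncertainty slightly by ignoring weight
  estimation; use the bootstrap for final reported intervals.
* The mediator weight model assumes log-normal intake given covariates; with
  heavy-tailed real diary data the density ratio can be unstable in the
  tails (the 1%/99% truncation is the guard).
* Single exposure/mediator pair only: no time-varying regimes, no
  doubly-robust or TMLE estimators, no survey design weights.
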