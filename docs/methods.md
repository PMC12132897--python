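# Methods

## Overview

`cacscreen` compares two CHD screening policies on a common cohort:

1. **Guideline (PCE ± CAC).** Ten-year atherosclerotic risk from the
   pooled cohort equations; categories low (<5%), borderline
   (5 to <7.5%), intermediate (7.5 to <20%), high (≥20%), all intervals
   closed on the left. Everyone is visited (the equations need labs and
   vitals); the intermediate category is CT-scanned; treatment
   eligibility = high ∪ (intermediate ∧ CACS ≥ 100 AU). Borderline
   individuals are never scanned or treated — the simplification is
   deliberate and kept as-is.
2. **Self-report + CAC rank.** A boosted-stump model predicts
   P(CACS ≥ 100) from ten self-report factors; the top *n*₁ by predicted
   probability are scanned (these are the only health-care contacts);
   the scanned are re-ranked by measured CACS and the top *n*₂ are
   treatment eligible. With (*n*₁, *n*₂) set to the guideline pathway's
   scan and treatment counts, resource use is matched by construction.
   Fixed-threshold variants replace the caps with absolute cutoffs
   (scan if predicted probability > p, treat if CACS > c, both strict);
   presets conservative (0.20, 20), intermediate (0.18, 15) and liberal
   (0.15, 0) span the studied range.

The headline measure is event capture: the percentage of all 10-year
events occurring in the treatment-eligible group. Matched-resource
strategies are compared with McNemar's test on the paired eligibility
of event-positive participants (b = events eligible under A only,
c = under B only; continuity-corrected chi-square, exact binomial when
b + c < 25 — the cutover is the usual small-sample rule). Model
discrimination is the rank-based AUC (ties counted half).

## PCE engine

Coefficients follow the 2013 ACC/AHA risk-assessment equations: four
sex × race-group equations (White/other and Black). Chinese and
Hispanic participants are scored with the White/other equations, the
convention of the source equations. Risk = 1 − S₁₀^exp(LP − mean LP).
The coefficient file is shipped as YAML (SHA-256 recorded in every run
manifest); the test suite holds a second, independently entered copy
plus the source's published worked risk profiles, so a transcription
error in either copy fails the build. The diabetes term is carried but
fixed to zero: the emulated population excludes diabetes. Inputs are
validated to the equations' stated domain (age 40–79, positive labs);
upstream exclusions guarantee 45–75.

## Self-report model

Gradient boosting with the reference defaults: 100 trees, depth 1,
shrinkage 0.1, bag fraction 0.5, Bernoulli deviance, no early stopping,
no hyperparameter tuning. Depth-1 trees make the raw score additive
over features, which the tests exploit directly. Race enters one-hot
over its four levels. Fold assignment for the 5-fold cross-validation
is label-stratified and seeded (stratification is a stability choice at
16% prevalence). Downstream ranking always uses the out-of-fold
predictions, never in-fold scores — the conservative reading of
"cross-validated" for honest resource allocation. The label threshold
is a parameter (default 100 AU; the secondary analysis threshold >0 AU
uses the same trainer). Relative-influence importances are normalised
to sum to 100%. The fitted ensemble serialises to a JSON stump list
(feature, split, left/right raw values, initial score) that reproduces
`predict_proba` exactly without the estimator object.

## Synthetic cohort generator

The generator emulates the *analysis population* of a multi-ethnic US
cohort study after its exclusion flow (no diabetes, no lipid-lowering
therapy, age ≤ 75), not the study's sampling design. Published
marginal targets, all checked by the test suite at n=10000:

| quantity | target | attained (n=200k) |
|---|---|---|
| mean age | 59.0 y | 59.0 |
| male | 46.5% | 46.5% |
| race White/Chinese/Black/Hispanic | 39.3/12.3/26.6/21.8% | exact draw probabilities |
| CACS = 0 | 59% | 58.9% |
| CACS ≥ 100 | 16.3% | 16.3% |
| 10-y events all CHD / hard CHD / all CVD / hard CVD | 4.7/2.9/6.7/5.2% | 4.6/2.9/6.5/5.1% |

Ages are a truncated normal on [45, 75] with a wide scale (near-flat
profile); the published age SD of 8.75 y slightly exceeds the maximum
any distribution on a 30-year window without endpoint mass can attain
(uniform gives 8.66), so the realised SD is ~8.2 and only the mean is
treated as a hard target.

**CAC** follows a two-part hurdle: logistic P(CACS=0) and log-normal
positive scores (σ = 1.55, ceiling 6000 AU), both driven by age, male
sex, log(pack-years+1), weight at 20, family history and race, with
age, pack-years and sex carrying the largest effects — the ordering
reported for the self-report model's variable importances, so
importance tests are meaningful.

**Events** are Bernoulli from one logistic model on standardised age,
SBP, total and HDL cholesterol, male sex, log(pack-years+1) and
log(CACS+1); the broadest endpoint (all CVD) is simulated and the
narrower endpoint sets are nested subsamples, which enforces the
subset relations between endpoint definitions by construction. The
log-CAC slope (0.55) dominates and the direct covariate effects are
modest. That balance is calibrated to the published *conditional*
anchors, not just the marginals: in the emulated study the PCE-high
stratum's event rate is only ~2.1× the population rate, while CAC
strata separate events much more sharply, and continuous smoking
history (invisible to the PCE, which sees only current smoking)
carries strong predictive value. Under these conditions the
CAC-rank-based strategy captures more events than the guideline
pathway in ~98% of seeded replicates (mean gap ≈ +4–5 pp), which is
the directional finding the simulation is designed to probe.

Intercepts (hurdle zero-rate, log-normal location, event model) were
frozen once from an n=200 000 simulation against the targets above.
Covariances are not published for the emulated cohort; the configured
joint structure (Gaussian copula ρ=0.4 between height and weight,
weight-at-20 = weight × Beta(17,3) shrinkage, smoking duration
consistent with pack-years, age slopes on SBP/cholesterol/hypertension
treatment) is an explicit assumption, adjustable through
`GeneratorConfig`. Marginals with no published value (height by sex,
45% ever-smokers, 30% of them current, pack-years log-normal around 12,
38% family history, ~20% antihypertensive use) are realistic choices
for a US screening population of this age band, stated here once and
not tuned.

The generator also simulates and drops excluded strata (age > 75,
lipid-lowering therapy, diabetes) through the same exclusion-ledger
arithmetic used to check the published inclusion flow; exclusion flags
are drawn independently of the retained covariates so the
post-exclusion marginals equal the configured ones.

### What the synthetic cohorts do and do not show

Passing tests demonstrate that the pipeline's logic is correct (exact
rule application, resource matching, honest ranking, correct paired
statistics) and that the directional advantage of CAC-rank-based
allocation emerges under the stated, published-anchor-calibrated
conditions. They do **not** re-estimate the real cohort's capture
fractions: synthetic capture percentages run higher than the published
ones (the single-logistic event model concentrates events in high-CAC
strata more than reality), and the synthetic event rate among
PCE-high participants with CACS=0 is near zero where the real cohort
shows ~4%, because one logistic model with a dominant CAC term cannot
simultaneously match that subgroup rate and the strong CAC gradient.
Real-data features not emulated: site effects, longitudinal exam
structure, competing risks and event times (binary 10-year indicators
only), missing data (generated tables are complete), and any
self-report recall error.

## Age/sex-adjusted sensitivity variant

`age_sex_adjusted_guideline_strategy` replaces the absolute CACS ≥ 100
rule for intermediate risk with "CACS > 0 and at or above the
empirical P-th percentile of the participant's sex × age-decade
stratum" (default 75th — the reference percentile tables behind the
published variant are not reproduced, so the percentile and stratum
definition are configurable, documented assumptions). Strata under 10
members fall back to the sex-only stratum.

## Numerical and reporting choices

- Deterministic tie-breaks everywhere: descending primary key,
  descending secondary key (predicted probability in the CACS
  re-rank), ascending participant id.
- Boundary semantics are comparator-exact and unit-tested: PCE
  categories closed on the left; guideline CAC rule ≥ 100;
  fixed-threshold cutoffs strict (>).
- One global pipeline seed spawns per-stage seeds via
  `numpy.random.SeedSequence`; identical configs reproduce reports
  byte for byte.
- Report percentages are printed to one decimal; raw fractions are
  retained in the JSON. No multiple-testing adjustment is applied to
  McNemar p-values (they are reported unadjusted, as is conventional
  for a single primary comparison with labelled sensitivity analyses).
- Printed-arithmetic verification rounds half-up to the printed
  precision and allows ±0.1 pp, absorbing half-up vs truncation
  ambiguity in the source (e.g. 373/1519 = 24.56% printed as 24.5%);
  such cases pass with an explicit `rounding-note` flag.

## Known limitations

- The synthetic cohorts are a stylised emulation; absolute capture
  fractions, treated-group event rates and AUCs on synthetic data are
  not estimates of any real cohort's values.
- The PCE implementation intentionally omits recalibration and other
  risk engines.
- Treatment effect is not modelled: "treatment eligible" is a
  classification, and event capture counts events, not events averted.
- The fixed-threshold presets assume the deployed model's probability
  scale matches the trained one; re-training on a different population
  shifts the operating points.
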