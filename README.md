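# cacscreen

Simulation and evaluation of coronary-heart-disease (CHD) screening
strategies that combine questionnaire-based risk assessment with
CT coronary artery calcium (CAC) scoring.

## The problem

Current primary-prevention guidelines start from the pooled cohort
equations (PCE): a clinic visit measures blood pressure and lipids, the
10-year atherosclerotic-risk estimate sorts people into low (<5%),
borderline (5 to <7.5%), intermediate (7.5 to <20%) and high (≥20%)
categories, intermediate-risk individuals get a CT scan, and
lipid-lowering therapy goes to the high-risk group plus
intermediate-risk individuals with a CAC score (CACS) ≥100 Agatston
units. This pathway requires an initial health-care visit for the
entire population.

An alternative is to screen first with *self-reported* factors only —
age, sex, race, body weight now and at age 20, height, cigarette
pack-years, smoking duration, antihypertensive medication, family
history of myocardial infarction — using a model that predicts the
probability of a high CAC score, CT-scan only the top-ranked
individuals, and grant treatment eligibility purely by the measured
CACS rank within the scanned group. With the number of scans and
treatments fixed to what the guideline pathway spends, the two
strategies can be compared head-to-head on **event capture**: the
fraction of all 10-year CHD events that occur in the treatment-eligible
group.

`cacscreen` implements both pathways, a gradient-boosted-stump
self-report model (100 depth-1 trees, shrinkage 0.1, bag fraction 0.5,
Bernoulli deviance, 5-fold cross-validated predictions), fixed-threshold
"real-world" variants, and the evaluation machinery (event capture,
McNemar's paired test on event-positive eligibility, AUC, calibration,
resource accounting). Because the cohorts such strategies are studied
on are access-restricted, the package ships a seeded synthetic-cohort
generator that reproduces the published marginal structure of a
multi-ethnic US screening population aged 45–75 without diabetes or
lipid-lowering therapy: ~59% CACS=0, ~16.3% CACS≥100 (zero-inflated
log-normal hurdle model), 4.7% 10-year CHD event rate, with event risk
strictly increasing in CACS. All downstream stages are therefore fully
testable offline.

## Worked example

```bash
cacscreen run-all --n 4564 --seed 20250321 --out out/
```

prints

```
guideline: capture 57.4% (116/202), visits 4564, scans 1475, treated 736
selfreport-benchmarked: capture 59.9% (121/202), visits 1475, scans 1475, treated 736
```

Reading: on this synthetic cohort of 4564 participants, the simplified
guideline pathway visits everyone, scans the 1475 intermediate-risk
participants and treats 736 (high risk, or intermediate with CACS≥100),
and 57.4% of the 202 ten-year CHD events occur in that treated group.
The self-report strategy, constrained to the *same* 1475 scans and 736
treatments, needs health-care visits only for the scanned third of the
population and captures 59.9% of events. `out/report.json` carries the
full evaluation (four endpoint sets × five strategies, McNemar
comparisons against the guideline, resource percentages); the other
files are the cohort, per-participant risk scores and per-strategy
eligibility flags.

The same stages are available as library functions
(`generate_cohort`, `score_cohort`, `train_cac_model`,
`guideline_strategy`, `selfreport_benchmarked_strategy`,
`fixed_threshold_strategy`, `endpoint_sweep`, …) and as individual CLI
subcommands (`simulate`, `pce`, `train`, `predict`, `run-strategy`,
`evaluate`, `verify-printed`).

## Notes

See `docs/methods.md` for the generator's model, its calibration
targets and stated assumptions, the PCE coefficient provenance, and
known limitations of the synthetic emulation.
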