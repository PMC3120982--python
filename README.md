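# calipermatch

Propensity-score pair matching within calipers on the logit of the
propensity score — plus the calibrated simulation machinery needed to ask
*how wide should the caliper be?*

## The problem

In observational studies, treated and untreated subjects differ
systematically at baseline. Propensity-score matching forms pairs of
treated and untreated subjects whose propensity scores
e(x) = P(Z=1 | X=x) are close, and estimates the average treatment effect
among the treated (ATT) from the matched sample. The most common
implementation matches on the logit of the estimated propensity score,
accepting a control only within a caliper of width

> γ × √((s²_T + s²_C)/2),

where s²_T and s²_C are the group variances of the logit propensity score.
The multiplier γ trades bias against variance: narrow calipers pair more
similar subjects but discard more of them. `calipermatch` provides

* the matching estimator itself (greedy 1:1 nearest-neighbour without
  replacement, seed-controlled processing order, exact tie-breaking) with
  McNemar-based inference for matched risk differences and paired-t
  inference for matched differences in means, behind a
  statsmodels-style model/results API;
* calibrated data-generating processes for binary and continuous outcomes
  over five covariate scenarios, in which intercepts and the conditional
  effect β are root-found so the marginal treatment prevalence (25%),
  untreated event rate (29%), and ATT hit exact targets;
* a Monte Carlo engine that sweeps γ and reports bias, percent bias
  reduction relative to the crude estimator, MSE, CI coverage, and type I
  error with binomial significance bands — the evaluation that underpins
  the standard γ = 0.2 recommendation;
* a synthetic heart-failure-like cohort generator (β-blocker exposure,
  one-year mortality) and a CLI for the cohort γ-sweep workflow.

It is written for biostatisticians and epidemiologists running matched
analyses or methods work on caliper choice.

## Worked example

Analyse a cohort at the recommended caliper, γ = 0.2:

```python
from calipermatch import CaliperMatch, generate_fixture

df = generate_fixture(n=7613, seed=1)          # synthetic HF cohort
model = CaliperMatch.from_dataframe(
    df, treatment="beta_blocker", outcome="death_1yr", outcome_kind="binary"
)
res = model.fit(gamma=0.2, order_seed=0)
print(res.summary())
```

```
Propensity-score caliper matching (ATT)
=======================================================
Estimand:            risk_difference
Caliper multiplier:  gamma = 0.2  (width 0.1253 on the logit scale)
Matched pairs:       2043  of 2064 treated subjects
Estimate:            -0.0240
Std. error:          0.0133
95% CI:              [-0.0500, 0.0020]
P-value (McNemar chi-square): 0.07108
-------------------------------------------------------
Worst pre-matching imbalance (standardized differences)
covariate                        pre    post
previous_mi                    0.293   0.000
copd                           0.270   0.022
age                            0.233   0.035
heart_rate                     0.169   0.036
dementia                       0.149   0.028
```

The matched estimate is a −2.4 percentage-point mortality difference
(CI crossing zero), against a crude difference of −7.2 points
(`model.crude().estimate` → −0.0720): most of the apparent benefit in this
synthetic cohort is confounding by indication, and matching removes the
covariate imbalance (standardized differences drop below 0.04). A
sensitivity sweep over γ is one call:

```python
print(model.sweep(gammas=(0.05, 0.2, 1.0, 2.5), order_seed=0).round(4))
```

```
 gamma  n_pairs  estimate     se  ci_low  ci_high  p_value
  0.05     2024   -0.0227 0.0134 -0.0489   0.0035   0.0895
  0.20     2043   -0.0240 0.0133 -0.0500   0.0020   0.0711
  1.00     2063   -0.0228 0.0132 -0.0486   0.0031   0.0842
  2.50     2064   -0.0228 0.0132 -0.0486   0.0031   0.0847
```

Simulation-side, one line calibrates a DGP to an exact marginal ATT and
one more runs a study:

```python
from calipermatch import StudySpec, run_study
table = run_study(StudySpec(outcome_kind="binary", true_effect=-0.05,
                            gammas=(0.2,), n_replicates=250))
print(table.table)   # bias, % bias reduction, MSE, coverage, rejection rate
```

The same workflows are available from the shell:

```bash
calipermatch fixture  --n 7613 --seed 1 --out cohort.csv
calipermatch apply    --cohort cohort.csv --treatment beta_blocker \
                      --outcome death_1yr --seed 0 --out sweep.csv
calipermatch calibrate --target-effect -0.02 --seed 0
calipermatch simulate --config study.yaml --seed 0 --out metrics.csv
```

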