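# Methods

## Scope and estimand

`calipermatch` implements 1:1 propensity-score matching within calipers on
the logit of the propensity score, together with the calibrated
data-generating processes (DGPs) and the Monte Carlo machinery needed to
study how the caliper width affects estimation. The estimand throughout is
the average treatment effect among the treated (ATT), expressed as a risk
difference for binary outcomes and a difference in means for continuous
ones. Odds ratios and relative risks are deliberately out of scope: matched
sampling targets the ATT, and difference-scale effects are collapsible,
which is what makes exact calibration of the DGP possible.

## Data-generating processes

Each simulated cohort has ten baseline covariates X1–X10 drawn under one of
five scenarios: independent standard normal; equicorrelated normal
(ρ = 0.25, via a Cholesky factor of the equicorrelation matrix); five
Bernoulli(0.5) plus five normal; nine Bernoulli(0.5) plus one normal; and
all Bernoulli(0.5). Binary covariates occupy the leading columns.

Treatment follows a logistic model, logit P(Z=1|x) = α₀,treat + x'α, and a
binary outcome follows logit P(Y=1|x,z) = α₀,outcome + βz + x'α. The
covariate coefficients come in four effect-size tiers — log(1.1),
log(1.25), log(1.5), log(2) — assigned 3/3/3/1 to X1–X3, X4–X6, X7–X9, and
X10. The tier-to-covariate assignment is not uniquely determined by the
marginal quantities the design fixes; the 3/3/3/1 pattern is adopted
because, with the linear-scale tiers 1.1/1.25/1.5/2 used by the continuous
outcome model, it gives Σα² = 19.0675 and hence variance explained
19.0675 / (19.0675 + 127.6056) = 0.1300 — exactly the 13% (R² = 0.13,
Cohen's "medium" effect) the continuous design specifies with residual
variance σ² = 127.6056. The same pattern is used in both logistic models.

The continuous outcome is Y = α₀,outcome + βz + x'α + ε with
ε ~ N(0, σ²), σ² = 127.6056 by default. Because differences in means are
collapsible, β *is* the ATT for continuous outcomes and needs no
calibration.

## Calibration

The binary-outcome DGP is calibrated to three marginal targets: treatment
prevalence 0.25, a marginal event rate of 0.29 were nobody treated, and a
specified ATT risk difference. Risk differences are collapsible, so the
marginal ATT equals the average over the treated population of the
subject-level risk difference expit(lp₀ + β) − expit(lp₀), where lp₀ is
the outcome linear predictor without treatment. The calibrator integrates
this by Monte Carlo over the covariate distribution (10⁶ draws by
default), weighting each draw by its treatment probability — the exact
expectation over treatment assignment — rather than sampling Z or Y, so
the only stochastic error left is the covariate draw.

Each parameter is solved by Brent's method on a fixed
common-random-numbers draw (treatment intercept on [−30, 30], β on
[−5, 5]); the objective is smooth and strictly monotone. Every
`CalibrationResult` re-evaluates the achieved marginal on an independent
draw and reports its Monte Carlo standard error; calibration aborts if the
achieved value misses the target by more than max(tolerance, 4 SE).

Two conventions deserve note:

* **Scale of β.** A protective risk difference requires a negative
  log-odds coefficient. The package solves β itself and reports exp(β)
  alongside; at targets −0.02 and −0.15 (independent-normal scenario,
  outcome intercept fixed at log(0.29/0.71)) the solved exp(β) is
  ≈ 0.9080 and ≈ 0.4688. The residual ~0.003 offset at −0.15 relative to
  historical constants for this design is consistent with the
  probability-weighted (rather than sampled) treated population used here
  and is far below the precision any downstream result depends on.
* **Outcome intercept.** For the independent-normal scenario the intercept
  is fixed at logit(0.29) and the realized marginal untreated rate is
  allowed to drift slightly (logit-normal mean > 0.29). For the other four
  scenarios all three parameters (α₀,treat, α₀,outcome, β) are re-solved,
  preserving prevalence, untreated marginal rate, and ATT, since changing
  the covariate distribution changes every induced marginal.

## Propensity model and matching

The propensity score is estimated by maximum-likelihood logistic
regression of treatment on the ten covariates (main effects only — the
model is correctly specified under the simulation DGPs). The linear
predictor is used directly as the logit propensity score. Non-convergence
or separation raises a diagnostic error naming suspect columns. A switch
(`StudySpec.match_on_true_ps`) allows matching on the true logit score for
diagnostic experiments.

The caliper width is γ × s_pool, where s_pool = sqrt((s²_T + s²_C)/2) with
sample variances (n−1 denominator) of the logit propensity score in the
two groups, computed on the full unmatched sample. The default γ grid is
0.05–2.50 in steps of 0.05 (50 widths).

Matching is greedy nearest-neighbour 1:1 without replacement: treated
subjects are processed in a random order drawn from an explicit order
seed (the order is part of the reproducibility contract), and each is
paired with the nearest still-unmatched control within the caliper, or
dropped. The matching algorithm itself is a design choice — greedy with
random processing order is the most common implementation in this
literature; optimal/full matching, 1:k, matching with replacement, and
probability-scale calipers are out of scope. Distance ties break toward
the lower control row index. The implementation keeps controls sorted by
logit score and answers nearest-surviving-neighbour queries with two
path-compressed pointer arrays, O(n log n) overall; it is verified
pair-for-pair against a naive quadratic reference, including engineered
tie configurations. Equal-value runs (common when all covariates are
binary and the score is discrete) are walked explicitly so tie-breaking
stays exact.

## Estimators and inference

With pair counts a (both events), b (treated only), c (control only),
d (neither), n = a+b+c+d:

* Matched risk difference: (b − c)/n, variance
  (b + c − (b − c)²/n)/n², Wald 95% CI with z = 1.959964, and McNemar's
  test (b − c)²/(b + c) on χ²₁, two-sided, without continuity correction
  (the large-sample correlated-proportions test; p = 1 when b + c = 0).
* Matched mean difference: mean of within-pair differences, SE sd(d)/√n,
  one-sample t with n − 1 df.
* Crude (unadjusted) contrasts on the full sample: difference in
  proportions with the two-sample binomial variance, or difference in
  means with Welch variance and Satterthwaite df.
* Balance: absolute standardized differences,
  |m₁ − m₀|/sqrt((s₁² + s₀²)/2), with Bernoulli variances for binary
  covariates. For user cohorts these are always computed from means/SDs
  (the standard definition), including for skewed variables that a table
  might summarize by medians.

## Monte Carlo engine

A study condition is (scenario, outcome kind, true ATT, n, replicate
count, γ grid, master seed). Each replicate derives its RNG stream from
(master seed, replicate index) via `numpy` seed sequences, making
replicate results a pure function of the spec — aggregation is
order-insensitive and runs can be parallelized or resumed externally.
Within a replicate, all γ values share one propensity fit and one treated
processing order.

Aggregation reports, per γ and for the crude estimator: mean estimate,
bias (vs the calibrated true effect), percent bias reduction
100(|bias_crude| − |bias_PS|)/|bias_crude| (absolute-value convention, so
a sign-flipping overshoot scores 0; undefined when the crude estimator is
unbiased), MSE, 95% CI coverage, and the rejection rate of the nominal 5%
test. Replicates where a γ yields no pairs contribute missing values and
are excluded from that γ's aggregates with a reported count. Binomial
significance bands, nominal ± 1.959964·sqrt(nominal(1−nominal)/R), flag
coverage/rejection rates that differ significantly from nominal; at
R = 1,000 these are (0.9365, 0.9635) and (0.0365, 0.0635). The
MSE-optimal γ is the grid argmin, ties to the smallest γ.

### Study sizes

The full-scale profile of this design — 1,000 replicates of n = 10,000
over 50 γ values and five scenarios — is available but long-running. The
package's standard profile, used by the test suite and the acceptance
script, is 250 replicates of n = 10,000 with either a single γ or the
coarse grid (0.1, 0.2, 0.3, 0.6, 1.0, 1.5, 2.0, 2.5), chosen dense near
γ = 0.2 where the MSE optimum sits and sparse in the flat tail. At 250
replicates the binomial bands are about ±2.7 percentage points, so
band-membership checks (type I error, coverage) and the coarse-grid MSE
argmin (asserted to within one grid step of 0.2) are the reproducible
analogues of the full-scale per-figure optima; exact per-effect optimal γ
values are not re-derivable at this replicate count and are taken as
inputs where needed.

## Synthetic case-study cohort

`generate_fixture` emulates a heart-failure discharge cohort in which the
exposure is a β-blocker prescription at discharge (target prevalence
27.3%) and the outcome death within one year (target marginal rate
27.7%): 17 binary history/exam covariates and 11 continuous vitals/labs
with published-summary-magnitude marginals, prescription and mortality
models sharing age, prior MI, COPD, dementia and related covariates so
that treated patients are systematically younger and healthier (crude
estimate markedly more protective than the matched one). Model intercepts
are solved on the realized covariate draw, so the expected rates hit the
targets exactly and realized rates differ only by binomial noise.

What it does *not* emulate: the joint distribution of a real registry,
within-patient clinical coherence between labs and history, missingness,
or any particular treatment-effect size. Passing tests on this fixture
demonstrate the pipeline's behaviour under realistic dimensionality and
confounding, not agreement with any registry analysis; its risk-difference
estimates are not reference values.

## Numerical choices and edge cases

* Root-finding tolerance 10⁻¹⁰ on solved parameters; calibration targets
  verified to max(10⁻⁴, 4 MC SE).
* z = 1.959964 (not 1.96) so published band constants reproduce to 4 dp.
* Degenerate logit scores (zero pooled SD) give caliper width 0 with a
  warning — exact matching.
* Matched mean difference requires ≥ 2 pairs; risk difference ≥ 1 pair;
  empty matched samples are legal matcher output but undefined for
  estimation.
* The matched risk-difference variance is clamped at 0 against negative
  rounding (it is algebraically non-negative; fuzz-tested).
* NNT is reported both exactly (1/|RD|) and rounded up.

## Known limitations

* Greedy matching is order-dependent by construction; the order seed makes
  this explicit rather than hiding it.
* No survival outcomes; the case-study outcome is treated as a plain
  binary indicator.
* No 1:k or replacement matching, no ATE weighting.
* Binary covariates in user cohorts must be pre-coded 0/1; there is no
  automatic dummy expansion.
* Percent bias reduction is noisy whenever the crude bias is small; the
  engine reports NaN below |bias_crude| = 10⁻¹² but values computed from
  a nearly unbiased crude estimator should be interpreted with care.
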