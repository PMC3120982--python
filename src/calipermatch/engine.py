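"""Monte Carlo evaluation of caliper widths.

One study condition = (covariate scenario, outcome kind, true ATT). For
each replicate a fresh cohort is simulated from the calibrated
data-generating process, the propensity model is fit by maximum likelihood,
a matched sample is formed at every gamma on the grid, and the matched and
crude effects are estimated. Replicates are pure functions of
(master seed, replicate index), so execution order is irrelevant and runs
can be resumed or distributed freely.

Aggregation reports, per gamma: mean estimate, bias, percent bias reduction
relative to the crude estimator, MSE, 95% CI coverage, the rejection rate
of the nominal 5% test, and the mean number of matched pairs. Binomial
significance bands qualify coverage/rejection rates against their nominal
values given the replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .scenarios import CoefficientSet, get_scenario, simulate_cohort
from .calibration import calibrate_dgp
from .matching import fit_propensity, match_gamma_grid, DEFAULT_GAMMA_GRID
from .estimation import (
    EffectEstimate,
    crude_effect,
    matched_mean_difference,
    matched_risk_difference,
    pair_table,
)

__all__ = [
    "StudySpec",
    "MetricTable",
    "run_replicate",
    "run_study",
    "aggregate",
    "pct_bias_reduction",
    "significance_band",
    "optimal_gamma",
    "COARSE_GAMMA_GRID",
]

#: reduced grid for scaled-down runs; dense near the region of interest
COARSE_GAMMA_GRID = (0.1, 0.2, 0.3, 0.6, 1.0, 1.5, 2.0, 2.5)

Z975 = 1.959964


@dataclass
class StudySpec:
    """Configuration of one Monte Carlo study condition.

    ``true_effect`` is the target ATT: a risk difference for binary
    outcomes, a difference in means for continuous ones. The full-scale
    profile of the original design is 1,000 replicates of n = 10,000 over 50
    gammas; the default here is a scaled-down profile (250 replicates,
    coarse grid) sized for routine runs.
    """

    scenario: str = "independent_normal"
    outcome_kind: str = "binary"
    true_effect: float = 0.0
    n_subjects: int = 10_000
    n_replicates: int = 250
    gammas: tuple = COARSE_GAMMA_GRID
    master_seed: int = 20100427
    match_on_true_ps: bool = False

    def __post_init__(self):
        get_scenario(self.scenario)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if len(self.gammas) == 0 or min(self.gammas) <= 0:
            raise ValueError("gammas must be non-empty and positive")
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gammas"] = list(self.gammas)
        return d


def _estimate_matched(matched, Y, outcome_kind) -> EffectEstimate | None:
    if matched.n_pairs == 0 or (outcome_kind == "continuous" and matched.n_pairs < 2):
        return None
    if outcome_kind == "binary":
        return matched_risk_difference(pair_table(matched, Y))
    return matched_mean_difference(matched, Y)


def run_replicate(spec: StudySpec, replicate_index: int, coeffs: CoefficientSet):
    """Simulate and analyse one replicate.

    Returns ``(per_gamma, crude)`` where ``per_gamma`` maps gamma to an
    :class:`EffectEstimate` (or None if no pairs formed). Deterministic in
    (spec.master_seed, replicate_index).
    """
    ss = np.random.SeedSequence([spec.master_seed, replicate_index])
    cohort_ss, order_ss = ss.spawn(2)
    cohort = simulate_cohort(spec.scenario, coeffs, spec.n_subjects, cohort_ss)
    if spec.match_on_true_ps:
        logit_ps = cohort.lp_treat
    else:
        logit_ps = fit_propensity(cohort.covariates, cohort.treatment).logit_ps
    order_rng = np.random.default_rng(order_ss)
    samples = match_gamma_grid(logit_ps, cohort.treatment, spec.gammas, order_rng)
    estimand = (
        "risk_difference" if spec.outcome_kind == "binary" else "mean_difference"
    )
    per_gamma = {
        ms.gamma: _estimate_matched(ms, cohort.outcome, spec.outcome_kind)
        for ms in samples
    }
    crude = crude_effect(cohort.treatment, cohort.outcome, estimand)
    return per_gamma, crude


def pct_bias_reduction(bias_crude: float, bias_ps: float) -> float:
    """Percent of the crude estimator's bias removed by matching:
    100 * (|bias_crude| - |bias_ps|) / |bias_crude|.

    Undefined (NaN) when the crude estimator is essentially unbiased.
    """
    if abs(bias_crude) < 1e-12:
        return float("nan")
    return 100.0 * (abs(bias_crude) - abs(bias_ps)) / abs(bias_crude)


def significance_band(nominal: float, n_replicates: int):
    """Normal-approximation binomial band around a nominal rate: rates
    outside it differ significantly (5% level) from nominal given the
    replicate count."""
    if not (0 < nominal < 1):
        raise ValueError("nominal rate must lie in (0, 1)")
    half = Z975 * np.sqrt(nominal * (1 - nominal) / n_replicates)
    return float(nominal - half), float(nominal + half)


@dataclass
class MetricTable:
    """Aggregated Monte Carlo metrics for one study condition.

    ``table`` has one row per gamma plus a ``crude`` row; ``replicates``
    retains the replicate-level estimates (long format) for re-aggregation.
    """

    spec: StudySpec
    table: pd.DataFrame
    replicates: pd.DataFrame

    def row(self, gamma) -> pd.Series:
        key = "crude" if gamma == "crude" else float(gamma)
        return self.table.set_index("gamma").loc[key]


def aggregate(spec: StudySpec, replicate_outputs) -> MetricTable:
    """Fold replicate estimates into the metric table.

    bias = mean(estimate) - true effect; MSE = mean squared error around
    the true effect; coverage = share of 95% CIs containing it; rejection
    rate = share of replicates with p < 0.05. Replicates in which a gamma
    produced no matched pairs are excluded from that gamma's aggregates
    (their count is reported in ``n_missing``).
    """
    rows = []
    for rep, (per_gamma, crude) in enumerate(replicate_outputs):
        rows.append(
            dict(replicate=rep, gamma="crude", estimate=crude.estimate,
                 ci_low=crude.ci_low, ci_high=crude.ci_high,
                 p_value=crude.p_value, n_pairs=np.nan)
        )
        for g, est in per_gamma.items():
            if est is None:
                rows.append(dict(replicate=rep, gamma=float(g), estimate=np.nan,
                                 ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                                 n_pairs=0))
            else:
                rows.append(dict(replicate=rep, gamma=float(g),
                                 estimate=est.estimate, ci_low=est.ci_low,
                                 ci_high=est.ci_high, p_value=est.p_value,
                                 n_pairs=est.n_pairs))
    long = pd.DataFrame(rows)
    theta = spec.true_effect

    def _summarise(df):
        ok = df.dropna(subset=["estimate"])
        est = ok["estimate"].to_numpy()
        out = {
            "mean_estimate": est.mean() if est.size else np.nan,
            "bias": est.mean() - theta if est.size else np.nan,
            "mse": np.mean((est - theta) ** 2) if est.size else np.nan,
            "coverage": ((ok.ci_low <= theta) & (theta <= ok.ci_high)).mean()
            if est.size
            else np.nan,
            "rejection_rate": (ok.p_value < 0.05).mean() if est.size else np.nan,
            "mean_n_pairs": ok.n_pairs.mean(),
            "n_effective": est.size,
            "n_missing": int(df.shape[0] - est.size),
        }
        return pd.Series(out)

    summary = (
        long.groupby("gamma", sort=False).apply(_summarise, include_groups=False).reset_index()
    )
    crude_bias = float(summary.loc[summary.gamma == "crude", "bias"].iloc[0])
    summary["pct_bias_reduction"] = [
        np.nan if g == "crude" else pct_bias_reduction(crude_bias, b)
        for g, b in zip(summary.gamma, summary.bias)
    ]
    # order: gammas ascending, crude last
    gam = summary[summary.gamma != "crude"].copy()
    gam = gam.sort_values("gamma", key=lambda s: s.astype(float))
    summary = pd.concat([gam, summary[summary.gamma == "crude"]], ignore_index=True)
    cols = ["gamma", "mean_n_pairs", "mean_estimate", "bias", "pct_bias_reduction",
            "mse", "coverage", "rejection_rate", "n_effective", "n_missing"]
    return MetricTable(spec=spec, table=summary[cols], replicates=long)


def run_study(
    spec: StudySpec,
    coeffs: CoefficientSet | None = None,
    calibration_draws: int = 10**6,
    progress: bool = False,
) -> MetricTable:
    """Calibrate (unless coefficients are supplied), run all replicates, and
    aggregate."""
    if coeffs is None:
        coeffs, _ = calibrate_dgp(
            scenario=spec.scenario,
            outcome_kind=spec.outcome_kind,
            target_effect=spec.true_effect,
            mc_draws=calibration_draws,
            seed=spec.master_seed,
        )
    outputs = []
    for rep in range(spec.n_replicates):
        outputs.append(run_replicate(spec, rep, coeffs))
        if progress and (rep + 1) % 50 == 0:
            import sys

            print(f"  replicate {rep + 1}/{spec.n_replicates}", file=sys.stderr)
    return aggregate(spec, outputs)


def optimal_gamma(table: MetricTable | pd.DataFrame, criterion: str = "mse") -> float:
    """Gamma minimising MSE (or maximising percent bias reduction) over the
    grid; ties resolve to the smallest gamma."""
    df = table.table if isinstance(table, MetricTable) else table
    df = df[df.gamma != "crude"].copy()
    df["gamma"] = df["gamma"].astype(float)
    df = df.sort_values("gamma")
    if criterion == "mse":
        best = df.mse.min()
        return float(df.loc[df.mse == best, "gamma"].iloc[0])
    if criterion == "bias_reduction":
        best = df.pct_bias_reduction.max()
        return float(df.loc[df.pct_bias_reduction == best, "gamma"].iloc[0])
    raise ValueError("criterion must be 'mse' or 'bias_reduction'")
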