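"""Calibration of the data-generating process to marginal targets.

The simulation design fixes three marginal quantities: the treatment
prevalence (default 0.25), the marginal event rate if nobody were treated
(default 0.29, binary outcomes), and the ATT — the average treatment effect
among the treated, expressed as a risk difference (binary) or a difference
in means (continuous). Intercepts and the conditional treatment coefficient
beta are solved numerically so the induced marginals hit those targets.

Because the risk difference is collapsible, the marginal ATT equals the
average over treated subjects of the subject-level risk difference
expit(lp0 + beta) - expit(lp0), which can be integrated by Monte Carlo over
the covariate distribution without simulating outcomes. Each subject is
weighted by its treatment probability, which is the exact expectation over
treatment assignment as well. Root finding uses Brent's method on a fixed
(common-random-numbers) covariate draw, so the objective is smooth,
monotone, and deterministic given the seed.

Note on scale: a protective effect (negative risk difference) corresponds to
a negative log-odds beta; results record both beta and exp(beta), the
conditional odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .scenarios import (
    CoefficientSet,
    default_coefficients,
    generate_covariates,
    get_scenario,
    outcome_linear_predictor,
    treatment_probability,
)

__all__ = [
    "CalibrationResult",
    "att_risk_difference",
    "calibrate_beta",
    "calibrate_treatment_intercept",
    "calibrate_outcome_intercept",
    "calibrate_dgp",
    "induced_r_squared",
    "sigma2_for_r_squared",
    "nnt_from_rd",
    "NNT",
]

DEFAULT_MC_DRAWS = 10**6
_BRACKET = (-5.0, 5.0)
_TOL = 1e-10  # root tolerance on the solved parameter


@dataclass
class CalibrationResult:
    """A solved DGP parameter together with its achieved marginal target.

    ``achieved`` and ``mc_standard_error`` are evaluated on an independent
    Monte Carlo draw (different stream from the one used for root finding).
    """

    parameter_name: str
    solved_value: float
    target: float
    achieved: float
    mc_draws: int
    mc_standard_error: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _draw(scenario, mc_draws, seed):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return generate_covariates(scenario, mc_draws, np.random.default_rng(ss))


def _att_rd_from_lp(lp0: np.ndarray, w: np.ndarray, beta: float) -> float:
    """Treatment-probability-weighted mean of subject-level risk differences."""
    rd = expit(lp0 + beta) - expit(lp0)
    return float(np.average(rd, weights=w))


def att_risk_difference(
    coeffs: CoefficientSet,
    beta: float,
    scenario="independent_normal",
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
    _X: np.ndarray | None = None,
) -> float:
    """Marginal ATT risk difference induced by a conditional effect ``beta``.

    Integrates expit(lp0 + beta) - expit(lp0) over the covariate
    distribution, weighting subjects by their treatment probability (the
    treated population defines the ATT). No outcome sampling is involved, so
    the only Monte Carlo error comes from the covariate draw.
    """
    if mc_draws < 10**4:
        import warnings

        warnings.warn(
            "mc_draws below 1e4 gives an unreliable ATT integral", stacklevel=2
        )
    X = _X if _X is not None else _draw(scenario, mc_draws, seed)
    _, w = treatment_probability(X, coeffs)
    lp0 = outcome_linear_predictor(X, coeffs)
    return _att_rd_from_lp(lp0, w, beta)


def _weighted_mean_se(values: np.ndarray, weights: np.ndarray):
    """Weighted mean and its Monte Carlo standard error (delta method)."""
    n = values.size
    wbar = weights.mean()
    m = float(np.average(values, weights=weights))
    infl = weights * (values - m) / wbar
    se = float(infl.std(ddof=1) / math.sqrt(n))
    return m, se


def calibrate_beta(
    target_rd: float,
    coeffs: CoefficientSet,
    scenario="independent_normal",
    tolerance: float = 1e-4,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
) -> CalibrationResult:
    """Solve the conditional effect beta for a target marginal ATT risk
    difference.

    Brent root finding on a single common-random-numbers covariate draw;
    ``achieved`` is re-evaluated on a fresh draw. ``solved_value`` is beta on
    the log-odds scale; exp(beta) is the conditional odds ratio.
    """
    sc = get_scenario(scenario)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence([seed])
    solve_ss, check_ss = ss.spawn(2)
    X = _draw(sc, mc_draws, solve_ss)
    _, w = treatment_probability(X, coeffs)
    lp0 = outcome_linear_predictor(X, coeffs)

    if target_rd == 0.0:
        beta = 0.0
    else:
        f = lambda b: _att_rd_from_lp(lp0, w, b) - target_rd
        lo, hi = _BRACKET
        if f(lo) * f(hi) > 0:
            raise ValueError(
                f"target risk difference {target_rd} not attainable within "
                f"beta in [{lo}, {hi}]"
            )
        beta = float(brentq(f, lo, hi, xtol=_TOL))

    Xc = _draw(sc, mc_draws, check_ss)
    _, wc = treatment_probability(Xc, coeffs)
    lp0c = outcome_linear_predictor(Xc, coeffs)
    rd = expit(lp0c + beta) - expit(lp0c)
    achieved, se = _weighted_mean_se(rd, wc)
    res = CalibrationResult(
        parameter_name="beta",
        solved_value=beta,
        target=target_rd,
        achieved=achieved,
        mc_draws=mc_draws,
        mc_standard_error=se,
        seed=seed if isinstance(seed, int) else -1,
    )
    if abs(achieved - target_rd) > max(tolerance, 4 * se):
        raise RuntimeError(
            f"calibrated beta misses target: achieved {achieved:.6f} vs "
            f"target {target_rd:.6f} (MC se {se:.2e})"
        )
    return res


def _calibrate_intercept(
    which: str,
    target: float,
    coeffs: CoefficientSet,
    scenario,
    mc_draws: int,
    seed,
) -> CalibrationResult:
    if not (0.0 < target < 1.0):
        raise ValueError("target probability must lie in (0, 1)")
    sc = get_scenario(scenario)
    ss = np.random.SeedSequence([seed]) if isinstance(seed, int) else seed
    solve_ss, check_ss = ss.spawn(2)
    X = _draw(sc, mc_draws, solve_ss)
    coef = coeffs.treat_coefs if which == "treat" else coeffs.outcome_coefs
    eta = X @ coef

    f = lambda a0: float(expit(a0 + eta).mean()) - target
    lo, hi = -30.0, 30.0
    a0 = float(brentq(f, lo, hi, xtol=_TOL))

    Xc = _draw(sc, mc_draws, check_ss)
    p = expit(a0 + Xc @ coef)
    achieved = float(p.mean())
    se = float(p.std(ddof=1) / math.sqrt(mc_draws))
    return CalibrationResult(
        parameter_name=f"intercept_{which}",
        solved_value=a0,
        target=target,
        achieved=achieved,
        mc_draws=mc_draws,
        mc_standard_error=se,
        seed=seed if isinstance(seed, int) else -1,
    )


def calibrate_treatment_intercept(
    target_prevalence: float,
    coeffs: CoefficientSet,
    scenario="independent_normal",
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
) -> CalibrationResult:
    """Solve the treatment-model intercept for a target marginal prevalence
    E[expit(a0 + x'alpha)] = target."""
    return _calibrate_intercept("treat", target_prevalence, coeffs, scenario, mc_draws, seed)


def calibrate_outcome_intercept(
    target_rate: float,
    coeffs: CoefficientSet,
    scenario="independent_normal",
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
) -> CalibrationResult:
    """Solve the outcome-model intercept so the marginal event rate, were
    nobody treated, equals the target."""
    return _calibrate_intercept("outcome", target_rate, coeffs, scenario, mc_draws, seed)


def calibrate_dgp(
    scenario="independent_normal",
    outcome_kind: str = "binary",
    target_effect: float = 0.0,
    target_prevalence: float = 0.25,
    target_untreated_rate: float = 0.29,
    fix_outcome_intercept: bool | None = None,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 0,
) -> tuple[CoefficientSet, dict]:
    """Fully calibrated coefficient set for one study condition.

    Binary outcomes: the treatment intercept is solved for the prevalence
    target; the outcome intercept is either fixed at logit(target rate) —
    the default for the independent-normal scenario, matching the original
    design — or solved for the marginal untreated rate (default for the
    other scenarios, whose covariates change the induced marginal); beta is
    then solved for the target ATT risk difference. Continuous outcomes:
    beta equals the target difference in means exactly (collapsible), the
    outcome intercept is 0 and only the treatment intercept is solved.

    Returns the coefficient set and a dict of :class:`CalibrationResult`.
    """
    sc = get_scenario(scenario)
    if fix_outcome_intercept is None:
        fix_outcome_intercept = sc.name == "independent_normal"
    coeffs = default_coefficients(outcome_kind)
    records: dict[str, CalibrationResult] = {}

    ss = np.random.SeedSequence([seed])
    seeds = ss.spawn(3)

    r_treat = _calibrate_intercept(
        "treat", target_prevalence, coeffs, sc, mc_draws, seeds[0]
    )
    coeffs.intercept_treat = r_treat.solved_value
    records["intercept_treat"] = r_treat

    if outcome_kind == "binary":
        if fix_outcome_intercept:
            coeffs.intercept_outcome = float(
                np.log(target_untreated_rate / (1 - target_untreated_rate))
            )
        else:
            r_out = _calibrate_intercept(
                "outcome", target_untreated_rate, coeffs, sc, mc_draws, seeds[1]
            )
            coeffs.intercept_outcome = r_out.solved_value
            records["intercept_outcome"] = r_out
        r_beta = calibrate_beta(
            target_effect, coeffs, sc, mc_draws=mc_draws, seed=seeds[2]
        )
        coeffs.beta = r_beta.solved_value
        records["beta"] = r_beta
    else:
        coeffs.intercept_outcome = 0.0
        coeffs.beta = float(target_effect)

    return coeffs, records


def induced_r_squared(coeffs: CoefficientSet, scenario="independent_normal") -> float:
    """Fraction of outcome variance explained by the covariates in the
    continuous model: alpha' Sigma alpha / (alpha' Sigma alpha + sigma2)."""
    if coeffs.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    cov = get_scenario(scenario).covariance_matrix()
    explained = float(coeffs.outcome_coefs @ cov @ coeffs.outcome_coefs)
    return explained / (explained + coeffs.sigma2)


def sigma2_for_r_squared(
    target_r2: float, coeffs: CoefficientSet, scenario="independent_normal"
) -> float:
    """Residual variance producing a given covariate R^2; exact inverse of
    :func:`induced_r_squared`."""
    if not (0.0 < target_r2 < 1.0):
        raise ValueError("target R^2 must lie in (0, 1)")
    cov = get_scenario(scenario).covariance_matrix()
    explained = float(coeffs.outcome_coefs @ cov @ coeffs.outcome_coefs)
    return explained * (1.0 - target_r2) / target_r2


@dataclass(frozen=True)
class NNT:
    """Number needed to treat: reciprocal absolute risk difference, with its
    conventional rounded-up integer."""

    exact: float
    ceiling: int

    def __float__(self):
        return self.exact


def nnt_from_rd(rd: float) -> NNT:
    """Number needed to treat for an absolute risk difference."""
    if rd == 0:
        raise ValueError("NNT undefined for a null risk difference")
    exact = 1.0 / abs(rd)
    return NNT(exact=exact, ceiling=math.ceil(exact - 1e-12))
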