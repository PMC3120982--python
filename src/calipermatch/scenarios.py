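"""Covariate scenarios and the calibrated data-generating processes.

Cohorts of ``n`` subjects carry ten baseline covariates X1..X10. Treatment
assignment follows a logistic model in the covariates; outcomes are either
Bernoulli draws from a logistic model in the covariates plus a treatment
term, or Gaussian draws around a linear predictor. Coefficients come in four
effect-size tiers (low/medium/high/very high), three covariates per tier for
the first three tiers and one for the last.

The binary-outcome process is built around collapsibility of the risk
difference: the average of subject-level risk differences among the treated
equals the marginal (population) risk difference in that group, so a
conditional logistic model can be calibrated to induce an exact marginal ATT
(see :mod:`calipermatch.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SCENARIO_NAMES",
    "CovariateScenario",
    "CoefficientSet",
    "SimulatedCohort",
    "get_scenario",
    "default_coefficients",
    "generate_covariates",
    "assign_treatment",
    "simulate_binary_outcomes",
    "simulate_continuous_outcomes",
    "simulate_cohort",
]

N_COVARIATES = 10

#: tier multipliers: low, medium, high, very high
TIER_VALUES = {"L": 1.1, "M": 1.25, "H": 1.5, "VH": 2.0}

#: default tier assignment for X1..X10: 3 low, 3 medium, 3 high, 1 very high
DEFAULT_ASSIGNMENT = ("L", "L", "L", "M", "M", "M", "H", "H", "H", "VH")

SCENARIO_NAMES = (
    "independent_normal",
    "correlated_normal",
    "mixed_5b5n",
    "mixed_9b1n",
    "all_binary",
)


@dataclass(frozen=True)
class CovariateScenario:
    """Marginal/joint distribution of the ten baseline covariates.

    Parameters
    ----------
    name : str
        One of ``SCENARIO_NAMES``.
    correlation : float
        Pairwise correlation among normal covariates (equicorrelation);
        nonzero only for ``correlated_normal``.
    n_binary : int
        Number of leading Bernoulli covariates; the remainder are standard
        normal.
    bernoulli_p : float
        Success probability of the Bernoulli covariates.
    """

    name: str
    correlation: float = 0.0
    n_binary: int = 0
    bernoulli_p: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_binary not in (0, 5, 9, 10):
            raise ValueError("n_binary must be one of 0, 5, 9, 10")

    @property
    def n_normal(self) -> int:
        return N_COVARIATES - self.n_binary

    def covariate_variances(self) -> np.ndarray:
        """Marginal variance of each covariate column."""
        v = np.ones(N_COVARIATES)
        v[: self.n_binary] = self.bernoulli_p * (1.0 - self.bernoulli_p)
        return v

    def covariance_matrix(self) -> np.ndarray:
        """Joint covariance of the covariate vector."""
        cov = np.diag(self.covariate_variances())
        if self.correlation:
            k = self.n_binary
            block = np.full((self.n_normal, self.n_normal), self.correlation)
            np.fill_diagonal(block, 1.0)
            cov[k:, k:] = block
        return cov


_SCENARIOS = {
    "independent_normal": CovariateScenario("independent_normal"),
    "correlated_normal": CovariateScenario("correlated_normal", correlation=0.25),
    "mixed_5b5n": CovariateScenario("mixed_5b5n", n_binary=5),
    "mixed_9b1n": CovariateScenario("mixed_9b1n", n_binary=9),
    "all_binary": CovariateScenario("all_binary", n_binary=10),
}


def get_scenario(name: str | CovariateScenario) -> CovariateScenario:
    if isinstance(name, CovariateScenario):
        return name
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown covariate scenario {name!r}; expected one of {SCENARIO_NAMES}"
        ) from None


@dataclass
class CoefficientSet:
    """Coefficients of the treatment- and outcome-generating models.

    ``treat_coefs`` are always on the log-odds scale. ``outcome_coefs`` are
    log-odds for a binary outcome and outcome units for a continuous one.
    ``beta`` is the conditional treatment effect (log-odds or outcome units);
    ``sigma2`` is the residual variance of a continuous outcome.
    """

    outcome_kind: str  # "binary" | "continuous"
    treat_coefs: np.ndarray
    outcome_coefs: np.ndarray
    intercept_treat: float = 0.0
    intercept_outcome: float = 0.0
    beta: float = 0.0
    sigma2: float = 0.0
    assignment: tuple = DEFAULT_ASSIGNMENT

    def __post_init__(self):
        self.treat_coefs = np.asarray(self.treat_coefs, dtype=float)
        self.outcome_coefs = np.asarray(self.outcome_coefs, dtype=float)
        if self.treat_coefs.shape != (N_COVARIATES,):
            raise ValueError(f"treat_coefs must have length {N_COVARIATES}")
        if self.outcome_coefs.shape != (N_COVARIATES,):
            raise ValueError(f"outcome_coefs must have length {N_COVARIATES}")
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")
        if self.outcome_kind == "continuous" and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive for a continuous outcome")


def _tier_vector(assignment, log_scale: bool) -> np.ndarray:
    vals = np.array([TIER_VALUES[t] for t in assignment], dtype=float)
    return np.log(vals) if log_scale else vals


def default_coefficients(
    outcome_kind: str = "binary",
    *,
    beta: float = 0.0,
    intercept_treat: float = 0.0,
    intercept_outcome: float | None = None,
    sigma2: float | None = None,
    assignment=DEFAULT_ASSIGNMENT,
) -> CoefficientSet:
    """Tiered default coefficient set.

    Binary outcome: both models use log(1.1)/log(1.25)/log(1.5)/log(2) tiers
    and the outcome intercept defaults to logit(0.29), the untreated marginal
    event rate. Continuous outcome: the outcome model uses 1.1/1.25/1.5/2 on
    the linear scale with residual variance 127.6056 (variance explained by
    the covariates then equals 13% under unit-variance covariates); the
    treatment model is unchanged.
    """
    if len(assignment) != N_COVARIATES:
        raise ValueError("assignment must cover all 10 covariates")
    treat = _tier_vector(assignment, log_scale=True)
    if outcome_kind == "binary":
        outc = _tier_vector(assignment, log_scale=True)
        if intercept_outcome is None:
            intercept_outcome = float(np.log(0.29 / 0.71))
        sigma2 = 0.0 if sigma2 is None else sigma2
    elif outcome_kind == "continuous":
        outc = _tier_vector(assignment, log_scale=False)
        if intercept_outcome is None:
            intercept_outcome = 0.0
        if sigma2 is None:
            sigma2 = 127.6056
    else:
        raise ValueError("outcome_kind must be 'binary' or 'continuous'")
    return CoefficientSet(
        outcome_kind=outcome_kind,
        treat_coefs=treat,
        outcome_coefs=outc,
        intercept_treat=intercept_treat,
        intercept_outcome=intercept_outcome,
        beta=beta,
        sigma2=sigma2,
        assignment=tuple(assignment),
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_covariates(scenario, n: int, seed=0) -> np.ndarray:
    """Draw an ``n x 10`` covariate matrix under a scenario.

    Normal columns are standard normal; under ``correlated_normal`` they are
    equicorrelated (rho = 0.25) via a Cholesky factor. Bernoulli columns are
    iid with the scenario's success probability and occupy the leading
    positions.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    sc = get_scenario(scenario)
    rng = _rng(seed)
    X = np.empty((n, N_COVARIATES))
    k = sc.n_binary
    if k:
        X[:, :k] = (rng.random((n, k)) < sc.bernoulli_p).astype(float)
    if sc.n_normal:
        Zn = rng.standard_normal((n, sc.n_normal))
        if sc.correlation:
            block = np.full((sc.n_normal, sc.n_normal), sc.correlation)
            np.fill_diagonal(block, 1.0)
            Zn = Zn @ np.linalg.cholesky(block).T
        X[:, k:] = Zn
    return X


def treatment_probability(covariates: np.ndarray, coeffs: CoefficientSet):
    """Linear predictor and probability of treatment for each subject."""
    lp = coeffs.intercept_treat + covariates @ coeffs.treat_coefs
    return lp, expit(lp)


def assign_treatment(covariates: np.ndarray, coeffs: CoefficientSet, seed=0):
    """Bernoulli treatment indicator from the logistic assignment model.

    Returns ``(Z, lp_treat)`` where ``lp_treat`` is the log-odds linear
    predictor.
    """
    rng = _rng(seed)
    lp, p = treatment_probability(covariates, coeffs)
    Z = (rng.random(covariates.shape[0]) < p).astype(np.int8)
    return Z, lp


def outcome_linear_predictor(covariates: np.ndarray, coeffs: CoefficientSet):
    """Outcome-model linear predictor excluding the treatment term."""
    return coeffs.intercept_outcome + covariates @ coeffs.outcome_coefs


def simulate_binary_outcomes(covariates, Z, coeffs: CoefficientSet, seed=0):
    """Bernoulli outcomes with P(Y=1|x,z) = expit(lp0(x) + beta*z)."""
    Z = np.asarray(Z)
    if Z.shape[0] != covariates.shape[0]:
        raise ValueError("Z must align with covariate rows")
    rng = _rng(seed)
    p = expit(outcome_linear_predictor(covariates, coeffs) + coeffs.beta * Z)
    return (rng.random(covariates.shape[0]) < p).astype(np.int8)


def simulate_continuous_outcomes(covariates, Z, coeffs: CoefficientSet, seed=0):
    """Gaussian outcomes Y = lp0(x) + beta*z + eps, eps ~ N(0, sigma2).

    Differences in means are collapsible, so ``beta`` is the ATT (and ATE)
    exactly.
    """
    if coeffs.sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    Z = np.asarray(Z)
    rng = _rng(seed)
    mu = outcome_linear_predictor(covariates, coeffs) + coeffs.beta * Z
    return mu + rng.standard_normal(covariates.shape[0]) * np.sqrt(coeffs.sigma2)


@dataclass
class SimulatedCohort:
    """One simulated replicate: covariates, treatment, outcome, and the true
    linear predictors they were generated from."""

    covariates: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    lp_treat: np.ndarray
    lp_outcome_base: np.ndarray
    outcome_kind: str
    seed: object = None

    @property
    def n(self) -> int:
        return self.covariates.shape[0]


def simulate_cohort(
    scenario,
    coeffs: CoefficientSet,
    n: int = 10_000,
    seed=0,
) -> SimulatedCohort:
    """Generate a complete cohort (covariates, treatment, outcome).

    A single seed (or :class:`numpy.random.SeedSequence`) is split into
    independent child streams for covariates, treatment, and outcomes, so the
    cohort is bit-reproducible given the seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cov_ss, trt_ss, out_ss = ss.spawn(3)
    X = generate_covariates(scenario, n, np.random.default_rng(cov_ss))
    Z, lp_treat = assign_treatment(X, coeffs, np.random.default_rng(trt_ss))
    lp0 = outcome_linear_predictor(X, coeffs)
    out_rng = np.random.default_rng(out_ss)
    if coeffs.outcome_kind == "binary":
        Y = simulate_binary_outcomes(X, Z, coeffs, out_rng)
    else:
        Y = simulate_continuous_outcomes(X, Z, coeffs, out_rng)
    return SimulatedCohort(
        covariates=X,
        treatment=Z,
        outcome=Y,
        lp_treat=lp_treat,
        lp_outcome_base=lp0,
        outcome_kind=coeffs.outcome_kind,
        seed=seed,
    )
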