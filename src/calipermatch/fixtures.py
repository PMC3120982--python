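"""Synthetic heart-failure-like cohort generator.

Emulates the demographic/clinical profile of a discharge cohort of patients
hospitalized with heart failure, where the exposure is a beta-blocker
prescription at discharge (~27.3% treated) and the outcome is death within
one year (~27.7%). Covariate marginals (17 binary history/exam variables,
11 continuous vitals and laboratory values) are set to published-summary
magnitudes for such cohorts, and confounding is induced by giving age,
prior myocardial infarction, COPD, dementia, and related variables roles in
both the prescription and the mortality model, with beta-blocker users
systematically younger and healthier.

This cohort is entirely synthetic: it reproduces marginal prevalences and a
realistic confounding structure, not any registry's joint distribution or
its treatment-effect estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["generate_fixture", "FIXTURE_SCHEMA", "fixture_schema"]

# name -> (mean, sd) for continuous covariates (units as clinically recorded)
_CONTINUOUS = {
    "age": (77.0, 10.5),
    "sbp": (150.0, 32.0),
    "heart_rate": (92.0, 24.0),
    "resp_rate": (24.5, 7.0),
    "hemoglobin": (124.0, 21.0),
    "wbc": (9.7, 3.6),
    "sodium": (138.7, 3.8),
    "potassium": (4.3, 0.7),
    "glucose": (8.9, 4.3),
    "bun": (9.6, 4.5),
    "creatinine": (115.0, 46.0),
}

# name -> prevalence for binary covariates
_BINARY = {
    "female": 0.502,
    "neck_vein_distension": 0.552,
    "s3": 0.099,
    "s4": 0.038,
    "rales": 0.104,
    "pulmonary_edema": 0.514,
    "cardiomegaly": 0.359,
    "diabetes": 0.351,
    "cva_tia": 0.160,
    "previous_mi": 0.368,
    "afib": 0.290,
    "pvd": 0.130,
    "copd": 0.166,
    "dementia": 0.067,
    "cirrhosis": 0.007,
    "cancer": 0.112,
    "lbbb": 0.148,
}

# log-odds of receiving a beta-blocker prescription, per standardized
# continuous unit or binary indicator; signs follow the usual prescribing
# pattern (healthier, post-MI patients treated; COPD/dementia contraindicate)
_TREAT_COEFS = {
    "age": -0.28,
    "sbp": 0.14,
    "heart_rate": -0.16,
    "resp_rate": -0.10,
    "hemoglobin": 0.05,
    "previous_mi": 0.62,
    "copd": -0.90,
    "dementia": -0.55,
    "afib": -0.25,
    "diabetes": 0.20,
    "pulmonary_edema": 0.18,
    "neck_vein_distension": 0.14,
    "cancer": -0.26,
    "cirrhosis": -1.0,
    "s3": 0.18,
}

# log-odds of death within one year; overlaps with the prescription model to
# induce confounding
_OUTCOME_COEFS = {
    "age": 0.55,
    "sbp": -0.25,
    "heart_rate": 0.12,
    "resp_rate": 0.18,
    "sodium": -0.18,
    "hemoglobin": -0.12,
    "bun": 0.30,
    "creatinine": 0.22,
    "previous_mi": 0.18,
    "copd": 0.35,
    "dementia": 0.65,
    "cancer": 0.55,
    "cirrhosis": 0.80,
    "afib": 0.15,
    "diabetes": 0.15,
    "pulmonary_edema": 0.20,
}

#: conditional log-odds ratio of death given a beta-blocker prescription
_TREATMENT_LOG_OR = -0.25

TARGET_TREATED_FRACTION = 0.273
TARGET_EVENT_RATE = 0.277


def fixture_schema():
    """CohortSchema describing the generated fixture table."""
    from .io import CohortSchema

    kinds = {name: "continuous" for name in _CONTINUOUS}
    kinds.update({name: "binary" for name in _BINARY})
    return CohortSchema(
        treatment_column="beta_blocker",
        outcome_column="death_1yr",
        outcome_kind="binary",
        covariate_columns=kinds,
    )


FIXTURE_SCHEMA = fixture_schema


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, b in coefs.items():
        if name in _CONTINUOUS:
            mu, sd = _CONTINUOUS[name]
            lp += b * (df[name].to_numpy() - mu) / sd
        else:
            lp += b * df[name].to_numpy()
    return lp


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    return brentq(lambda a: expit(a + lp).mean() - target, -20, 20, xtol=1e-10)


def generate_fixture(n: int = 7613, seed: int = 0) -> pd.DataFrame:
    """Generate the synthetic heart-failure cohort.

    Intercepts of the prescription and mortality models are solved on the
    realized covariate draw so the expected treated fraction and event rate
    hit 27.3% and 27.7%; the realized rates then differ only by binomial
    noise. Deterministic given ``(n, seed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    data = {}
    for name, (mu, sd) in _CONTINUOUS.items():
        x = rng.standard_normal(n) * sd + mu
        if name in ("wbc", "glucose", "bun", "creatinine", "potassium"):
            # right-skewed labs: floor well above zero
            x = np.maximum(x, mu * 0.2)
        data[name] = np.round(x, 1)
    for name, p in _BINARY.items():
        data[name] = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(data)

    lp_t = _linear_predictor(df, _TREAT_COEFS)
    a_t = _solve_intercept(lp_t, TARGET_TREATED_FRACTION)
    z = (rng.random(n) < expit(a_t + lp_t)).astype(int)

    lp_y = _linear_predictor(df, _OUTCOME_COEFS) + _TREATMENT_LOG_OR * z
    a_y = _solve_intercept(lp_y, TARGET_EVENT_RATE)
    y = (rng.random(n) < expit(a_y + lp_y)).astype(int)

    df["beta_blocker"] = z
    df["death_1yr"] = y
    return df
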