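"""Model/Results interface for caliper matching on a cohort.

:class:`CaliperMatch` is constructed from arrays or a DataFrame holding a
binary treatment, an outcome (binary or continuous), and covariates. Its
:meth:`~CaliperMatch.fit` estimates the ATT at one caliper multiplier and
returns a :class:`CaliperMatchResults` carrying the estimate, its standard
error, confidence interval, p-value, the matched sample, and balance
diagnostics; :meth:`~CaliperMatch.sweep` repeats the estimation over a grid
of gammas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matching import (
    DEFAULT_GAMMA_GRID,
    MatchedSample,
    PropensityFit,
    caliper_width,
    fit_propensity,
    greedy_match,
    match_gamma_grid,
)
from .estimation import (
    EffectEstimate,
    crude_effect,
    matched_mean_difference,
    matched_risk_difference,
    pair_table,
    standardized_difference,
)

__all__ = ["CaliperMatch", "CaliperMatchResults"]


class CaliperMatch:
    """Propensity-score pair matching within calipers on the logit scale.

    Parameters
    ----------
    outcome : array-like
        Outcome per subject; binary 0/1 or continuous according to
        ``outcome_kind``.
    treatment : array-like
        Binary treatment indicator.
    covariates : array-like, shape (n, p)
        Baseline covariates entering the propensity model as main effects.
    outcome_kind : {"binary", "continuous"}
        Chooses the estimand: matched risk difference with McNemar-based
        inference, or matched mean difference with paired-t inference.
    covariate_names, covariate_kinds : sequences, optional
        Names and {"continuous", "binary"} kinds used for balance
        diagnostics; kinds default to binary for 0/1-valued columns.
    """

    def __init__(
        self,
        outcome,
        treatment,
        covariates,
        outcome_kind: str = "binary",
        covariate_names=None,
        covariate_kinds=None,
    ):
        self.outcome = np.asarray(outcome, dtype=float)
        self.treatment = np.asarray(treatment)
        self.covariates = np.asarray(covariates, dtype=float)
        if self.covariates.ndim != 2:
            raise ValueError("covariates must be a 2-d array")
        n = self.covariates.shape[0]
        if self.outcome.shape[0] != n or self.treatment.shape[0] != n:
            raise ValueError("outcome, treatment and covariates must align")
        if not np.isin(self.treatment, (0, 1)).all():
            raise ValueError("treatment must be coded 0/1")
        if outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")
        if outcome_kind == "binary" and not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("binary outcome must be coded 0/1")
        self.outcome_kind = outcome_kind
        p = self.covariates.shape[1]
        self.covariate_names = (
            list(covariate_names)
            if covariate_names is not None
            else [f"x{j + 1}" for j in range(p)]
        )
        if covariate_kinds is None:
            covariate_kinds = [
                "binary" if np.isin(col, (0, 1)).all() else "continuous"
                for col in self.covariates.T
            ]
        self.covariate_kinds = list(covariate_kinds)
        self._propensity: PropensityFit | None = None

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        treatment: str,
        outcome: str,
        covariates=None,
        outcome_kind: str = "binary",
        covariate_kinds=None,
    ) -> "CaliperMatch":
        """Build the model from a cohort table; ``covariates`` defaults to
        every column other than treatment and outcome."""
        if covariates is None:
            covariates = [c for c in data.columns if c not in (treatment, outcome)]
        missing = [c for c in [treatment, outcome, *covariates] if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        return cls(
            outcome=data[outcome].to_numpy(),
            treatment=data[treatment].to_numpy(),
            covariates=data[list(covariates)].to_numpy(dtype=float),
            outcome_kind=outcome_kind,
            covariate_names=list(covariates),
            covariate_kinds=covariate_kinds,
        )

    @property
    def propensity(self) -> PropensityFit:
        """Fitted logistic propensity model (cached)."""
        if self._propensity is None:
            self._propensity = fit_propensity(
                self.covariates, self.treatment, self.covariate_names
            )
        return self._propensity

    def balance(self, matched: MatchedSample | None = None) -> pd.DataFrame:
        """Standardized differences per covariate, before matching or within
        a matched sample."""
        if matched is None:
            X, Z = self.covariates, self.treatment
        else:
            rows = np.concatenate([matched.treated_rows, matched.control_rows])
            X = self.covariates[rows]
            Z = np.concatenate(
                [np.ones(matched.n_pairs, dtype=int), np.zeros(matched.n_pairs, dtype=int)]
            )
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "kind": self.covariate_kinds,
                "std_diff": [
                    standardized_difference(X[:, j], Z, kind=k)
                    for j, k in enumerate(self.covariate_kinds)
                ],
            }
        )

    def _estimate(self, matched: MatchedSample) -> EffectEstimate:
        if self.outcome_kind == "binary":
            return matched_risk_difference(pair_table(matched, self.outcome))
        return matched_mean_difference(matched, self.outcome)

    def fit(self, gamma: float = 0.2, order_seed=0) -> "CaliperMatchResults":
        """Match at one caliper multiplier and estimate the ATT."""
        fitted = self.propensity
        width = caliper_width(fitted.logit_ps, self.treatment, gamma)
        matched = greedy_match(fitted.logit_ps, self.treatment, width, order_seed)
        matched.gamma = float(gamma)
        sd = width / gamma if gamma > 0 else np.nan
        matched.sd_pooled = sd
        if matched.n_pairs == 0:
            raise ValueError(
                f"no pairs formed at gamma={gamma}; widen the caliper"
            )
        est = self._estimate(matched)
        return CaliperMatchResults(self, matched, est)

    def sweep(self, gammas=DEFAULT_GAMMA_GRID, order_seed=0) -> pd.DataFrame:
        """Per-gamma matched estimates over a grid (one row per gamma).

        All gammas share one treated processing order, mirroring the
        gamma-sweep workflow used to study caliper-width sensitivity.
        """
        fitted = self.propensity
        samples = match_gamma_grid(fitted.logit_ps, self.treatment, gammas, order_seed)
        rows = []
        for ms in samples:
            if ms.n_pairs == 0 or (self.outcome_kind == "continuous" and ms.n_pairs < 2):
                rows.append(dict(gamma=ms.gamma, n_pairs=ms.n_pairs,
                                 estimate=np.nan, se=np.nan, ci_low=np.nan,
                                 ci_high=np.nan, p_value=np.nan))
                continue
            est = self._estimate(ms)
            rows.append(dict(gamma=ms.gamma, n_pairs=est.n_pairs,
                             estimate=est.estimate, se=est.se,
                             ci_low=est.ci_low, ci_high=est.ci_high,
                             p_value=est.p_value))
        return pd.DataFrame(rows)

    def crude(self) -> EffectEstimate:
        """Unadjusted effect on the full cohort."""
        estimand = (
            "risk_difference" if self.outcome_kind == "binary" else "mean_difference"
        )
        return crude_effect(self.treatment, self.outcome, estimand)


class CaliperMatchResults:
    """Results of caliper matching at one gamma.

    Attributes
    ----------
    estimate, se, pvalue, n_pairs : float / int
        ATT estimate (risk difference or mean difference), its standard
        error, two-sided p-value, and the number of matched pairs.
    matched_sample : MatchedSample
        The pairs the estimate was computed on.
    """

    def __init__(self, model: CaliperMatch, matched: MatchedSample, est: EffectEstimate):
        self.model = model
        self.matched_sample = matched
        self._est = est
        self.estimate = est.estimate
        self.se = est.se
        self.pvalue = est.p_value
        self.n_pairs = est.n_pairs
        self.gamma = matched.gamma
        self.caliper_width = matched.caliper_width

    def conf_int(self):
        return (self._est.ci_low, self._est.ci_high)

    @property
    def estimand(self) -> str:
        return self._est.estimand

    def balance_table(self) -> pd.DataFrame:
        """Pre- and post-matching standardized differences side by side."""
        pre = self.model.balance().rename(columns={"std_diff": "std_diff_pre"})
        post = self.model.balance(self.matched_sample)
        pre["std_diff_post"] = post["std_diff"]
        return pre

    def summary(self) -> str:
        est = self._est
        lo, hi = self.conf_int()
        test = "McNemar chi-square" if est.estimand == "risk_difference" else "paired t"
        lines = [
            "Propensity-score caliper matching (ATT)",
            "=" * 55,
            f"Estimand:            {est.estimand}",
            f"Caliper multiplier:  gamma = {self.gamma:g}"
            f"  (width {self.caliper_width:.4f} on the logit scale)",
            f"Matched pairs:       {self.n_pairs}"
            f"  of {int(np.sum(self.model.treatment == 1))} treated subjects",
            f"Estimate:            {self.estimate:.4f}",
            f"Std. error:          {self.se:.4f}",
            f"95% CI:              [{lo:.4f}, {hi:.4f}]",
            f"P-value ({test}): {self.pvalue:.4g}",
        ]
        bal = self.balance_table()
        worst = bal.sort_values("std_diff_pre", ascending=False).head(5)
        lines.append("-" * 55)
        lines.append("Worst pre-matching imbalance (standardized differences)")
        lines.append(f"{'covariate':<28}{'pre':>8}{'post':>8}")
        for _, r in worst.iterrows():
            lines.append(
                f"{r.covariate:<28}{r.std_diff_pre:>8.3f}{r.std_diff_post:>8.3f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CaliperMatchResults gamma={self.gamma:g} n_pairs={self.n_pairs} "
            f"estimate={self.estimate:.4f}>"
        )
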