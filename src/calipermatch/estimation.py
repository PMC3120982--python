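"""Effect estimators and inference for matched and unmatched samples.

Binary outcomes: the matched risk difference (b - c)/n with its
paired-proportions variance (b + c - (b - c)^2 / n) / n^2 and McNemar's
chi-square test on the discordant counts. Continuous outcomes: the mean of
within-pair differences with a one-sample t test. Crude (unadjusted)
estimators on the full sample and standardized-difference balance
diagnostics complete the set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .matching import MatchedSample

__all__ = [
    "PairTable",
    "EffectEstimate",
    "pair_table",
    "matched_risk_difference",
    "mcnemar_p",
    "matched_mean_difference",
    "crude_effect",
    "standardized_difference",
]

Z975 = 1.959964  # 97.5th normal percentile, conventional rounding


@dataclass(frozen=True)
class PairTable:
    """Concordant/discordant pair counts of a matched binary-outcome sample.

    a: both members with the event; b: treated only; c: control only;
    d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate with Wald/t inference for one estimand."""

    estimand: str  # "risk_difference" | "mean_difference"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def pair_table(matched: MatchedSample, Y) -> PairTable:
    """Cross-classify matched pairs by the binary outcomes of their members."""
    Y = np.asarray(Y)
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    yt = Y[matched.treated_rows]
    yc = Y[matched.control_rows]
    a = int(np.sum((yt == 1) & (yc == 1)))
    b = int(np.sum((yt == 1) & (yc == 0)))
    c = int(np.sum((yt == 0) & (yc == 1)))
    d = int(np.sum((yt == 0) & (yc == 0)))
    return PairTable(a, b, c, d)


def mcnemar_p(t: PairTable) -> float:
    """Two-sided McNemar test on the discordant counts, no continuity
    correction: (b - c)^2 / (b + c) against chi-square with 1 df.

    Returns 1 when there are no discordant pairs.
    """
    if t.n < 1:
        raise ValueError("empty pair table")
    disc = t.b + t.c
    if disc == 0:
        return 1.0
    stat = (t.b - t.c) ** 2 / disc
    return float(stats.chi2.sf(stat, df=1))


def matched_risk_difference(t: PairTable) -> EffectEstimate:
    """Matched-pairs risk difference (b - c)/n with paired-proportions
    variance and a McNemar p-value."""
    n = t.n
    if n < 1:
        raise ValueError("risk difference undefined for an empty matched sample")
    est = (t.b - t.c) / n
    var = (t.b + t.c - (t.b - t.c) ** 2 / n) / n**2
    se = float(np.sqrt(max(var, 0.0)))
    return EffectEstimate(
        estimand="risk_difference",
        estimate=float(est),
        se=se,
        ci_low=float(est - Z975 * se),
        ci_high=float(est + Z975 * se),
        p_value=mcnemar_p(t),
        n_pairs=n,
    )


def matched_mean_difference(matched: MatchedSample, Y) -> EffectEstimate:
    """Mean within-pair outcome difference with one-sample t inference
    (n - 1 degrees of freedom)."""
    Y = np.asarray(Y, dtype=float)
    n = matched.n_pairs
    if n < 2:
        raise ValueError("paired variance requires at least 2 pairs")
    d = Y[matched.treated_rows] - Y[matched.control_rows]
    est = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    tq = float(stats.t.ppf(0.975, df=n - 1))
    if se > 0:
        tstat = est / se
        p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
    else:
        p = 1.0 if est == 0 else 0.0
    return EffectEstimate(
        estimand="mean_difference",
        estimate=est,
        se=se,
        ci_low=est - tq * se,
        ci_high=est + tq * se,
        p_value=p,
        n_pairs=n,
    )


def crude_effect(Z, Y, estimand: str) -> EffectEstimate:
    """Unadjusted treated-vs-untreated contrast on the full sample.

    ``risk_difference``: difference in proportions with the two-sample
    binomial variance and a Wald z test. ``mean_difference``: difference in
    means with unpooled (Welch) variance and t inference.
    """
    Z = np.asarray(Z)
    Y = np.asarray(Y, dtype=float)
    y1, y0 = Y[Z == 1], Y[Z == 0]
    n1, n0 = y1.size, y0.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both treatment groups must be non-empty")
    est = float(y1.mean() - y0.mean())
    if estimand == "risk_difference":
        p1, p0 = y1.mean(), y0.mean()
        se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
        z = est / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
        lo, hi = est - Z975 * se, est + Z975 * se
    elif estimand == "mean_difference":
        v1, v0 = y1.var(ddof=1) / n1, y0.var(ddof=1) / n0
        se = float(np.sqrt(v1 + v0))
        if se > 0:
            # Welch-Satterthwaite degrees of freedom
            df = (v1 + v0) ** 2 / (v1**2 / (n1 - 1) + v0**2 / (n0 - 1))
            tq = float(stats.t.ppf(0.975, df=df))
            p = float(2 * stats.t.sf(abs(est / se), df=df))
        else:
            tq, p = 0.0, (1.0 if est == 0 else 0.0)
        lo, hi = est - tq * se, est + tq * se
    else:
        raise ValueError("estimand must be 'risk_difference' or 'mean_difference'")
    return EffectEstimate(
        estimand=estimand,
        estimate=est,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_pairs=0,
    )


def standardized_difference(values, Z, kind: str = "continuous") -> float:
    """Absolute standardized difference of a covariate between groups.

    Continuous: |m1 - m0| / sqrt((s1^2 + s0^2)/2). Binary: the same with
    Bernoulli variances p(1-p). A balance diagnostic, in pooled-SD units.
    """
    x = np.asarray(values, dtype=float)
    Z = np.asarray(Z)
    x1, x0 = x[Z == 1], x[Z == 0]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both groups must be non-empty")
    m1, m0 = x1.mean(), x0.mean()
    if kind == "binary":
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    elif kind == "continuous":
        v1 = x1.var(ddof=1) if x1.size > 1 else 0.0
        v0 = x0.var(ddof=1) if x0.size > 1 else 0.0
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if m1 == m0 else float("inf")
    return float(abs(m1 - m0) / denom)
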