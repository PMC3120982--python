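"""Matched-pair and crude estimators, inference, balance diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from calipermatch import (
    MatchedSample,
    PairTable,
    crude_effect,
    matched_mean_difference,
    matched_risk_difference,
    mcnemar_p,
    pair_table,
    standardized_difference,
)


def _sample(pairs):
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return MatchedSample(pairs=arr, gamma=0.2, caliper_width=0.1, sd_pooled=0.5)


class TestPairTable:
    def test_one_of_each(self):
        ms = _sample([[0, 1], [2, 3], [4, 5], [6, 7]])
        Y = np.array([1, 1, 1, 0, 0, 1, 0, 0])
        t = pair_table(ms, Y)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.n == 4

    def test_all_null_pairs(self):
        ms = _sample([[0, 1], [2, 3]])
        t = pair_table(ms, np.zeros(4, dtype=int))
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 2)

    def test_nonbinary_outcome_rejected(self):
        ms = _sample([[0, 1]])
        with pytest.raises(ValueError, match="binary"):
            pair_table(ms, np.array([0.5, 1.0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.integers(0, 10_000))
    def test_partition_property(self, n, seed):
        rng = np.random.default_rng(seed)
        ms = _sample(np.arange(2 * n).reshape(n, 2))
        Y = rng.integers(0, 2, 2 * n)
        t = pair_table(ms, Y)
        assert t.a + t.b + t.c + t.d == n


class TestMatchedRiskDifference:
    def test_direct_substitution(self):
        t = PairTable(a=10, b=25, c=5, d=60)
        est = matched_risk_difference(t)
        assert est.estimate == pytest.approx(0.20)
        assert est.se**2 == pytest.approx((30 - 400 / 100) / 100**2)
        assert est.se == pytest.approx(0.0510, abs=1e-4)
        assert est.ci_low == pytest.approx(0.20 - 1.959964 * est.se)

    def test_symmetric_discordance_is_null(self):
        est = matched_risk_difference(PairTable(3, 7, 7, 3))
        assert est.estimate == 0.0
        assert est.p_value == 1.0

    def test_estimate_equals_marginal_proportion_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, 4)
            if a + b + c + d == 0:
                continue
            t = PairTable(int(a), int(b), int(c), int(d))
            est = matched_risk_difference(t)
            assert est.estimate == pytest.approx((t.a + t.b) / t.n - (t.a + t.c) / t.n)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(*(st.integers(0, 500),) * 4)
    def test_variance_nonnegative_estimate_bounded(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        est = matched_risk_difference(PairTable(a, b, c, d))
        assert -1.0 <= est.estimate <= 1.0
        assert est.se >= 0.0
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            matched_risk_difference(PairTable(0, 0, 0, 0))


class TestMcNemar:
    def test_balanced_discordance(self):
        assert mcnemar_p(PairTable(0, 10, 10, 0)) == 1.0

    def test_chi2_tail_value(self):
        # b=15, c=5: statistic 5, upper tail of chi2_1
        p = mcnemar_p(PairTable(0, 15, 5, 0))
        assert p == pytest.approx(stats.chi2.sf(5, 1), rel=1e-12)
        assert p == pytest.approx(0.02535, abs=1e-4)

    def test_no_discordant_pairs(self):
        assert mcnemar_p(PairTable(5, 0, 0, 5)) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_depends_only_on_discordant_counts(self, a, b, c, d):
        base = mcnemar_p(PairTable(0, b, c, 1))
        assert mcnemar_p(PairTable(a, b, c, d + 1)) == base


class TestMatchedMeanDifference:
    def test_identical_outcomes_null(self):
        ms = _sample([[0, 1], [2, 3], [4, 5]])
        Y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        est = matched_mean_difference(ms, Y)
        assert est.estimate == 0.0
        assert est.p_value == 1.0

    def test_known_differences(self):
        ms = _sample([[0, 1], [2, 3], [4, 5]])
        Y = np.array([2.0, 1.0, 4.0, 2.0, 6.0, 3.0])  # differences 1, 2, 3
        est = matched_mean_difference(ms, Y)
        assert est.estimate == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(3), abs=1e-6)

    def test_matches_reference_t_test(self):
        rng = np.random.default_rng(1)
        n = 40
        ms = _sample(np.arange(2 * n).reshape(n, 2))
        Y = rng.standard_normal(2 * n)
        est = matched_mean_difference(ms, Y)
        d = Y[0::2] - Y[1::2]
        ref = stats.ttest_1samp(d, 0.0)
        assert est.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        lo, hi = ref.confidence_interval()
        assert est.ci_low == pytest.approx(lo, rel=1e-10)
        assert est.ci_high == pytest.approx(hi, rel=1e-10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            matched_mean_difference(_sample([[0, 1]]), np.array([1.0, 0.0]))


class TestCrudeEffect:
    def test_proportion_difference(self):
        Z = np.array([1] * 100 + [0] * 300)
        Y = np.array([1] * 40 + [0] * 60 + [1] * 90 + [0] * 210)
        est = crude_effect(Z, Y, "risk_difference")
        assert est.estimate == pytest.approx(0.10)

    def test_equal_group_means_null(self):
        Z = np.array([1, 1, 0, 0])
        Y = np.array([1.0, 3.0, 2.0, 2.0])
        est = crude_effect(Z, Y, "mean_difference")
        assert est.estimate == 0.0

    def test_agrees_with_matched_when_no_confounding(self):
        """Without confounding and with a homogeneous effect, crude and
        matched estimators estimate the same quantity."""
        rng = np.random.default_rng(2)
        n = 40_000
        Z = (rng.random(n) < 0.5).astype(int)
        Y = 1.5 * Z + rng.standard_normal(n)
        crude = crude_effect(Z, Y, "mean_difference")
        t_rows = np.flatnonzero(Z == 1)[: n // 4]
        c_rows = np.flatnonzero(Z == 0)[: n // 4]
        ms = _sample(np.column_stack([t_rows, c_rows]))
        matched = matched_mean_difference(ms, Y)
        assert crude.estimate == pytest.approx(1.5, abs=0.05)
        assert matched.estimate == pytest.approx(1.5, abs=0.05)


class TestStandardizedDifference:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        Z = np.array([1, 1, 1, 0, 0, 0])
        assert standardized_difference(x, Z) == 0.0

    def test_unit_shift_unit_variance(self):
        rng = np.random.default_rng(3)
        x0 = rng.standard_normal(100_000)
        x1 = rng.standard_normal(100_000) + 1.0
        x = np.concatenate([x1, x0])
        Z = np.repeat([1, 0], 100_000)
        assert standardized_difference(x, Z) == pytest.approx(1.0, abs=0.02)

    def test_binary_published_value(self):
        # prevalences 0.476 vs 0.328 give a standardized difference of 0.31
        n1, n0 = 2078, 5535
        x = np.concatenate([np.ones(989), np.zeros(n1 - 989), np.ones(1815), np.zeros(n0 - 1815)])
        Z = np.repeat([1, 0], [n1, n0])
        sd = standardized_difference(x, Z, kind="binary")
        assert sd == pytest.approx(0.31, abs=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-100, 100), st.integers(0, 1000))
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        Z = np.repeat([1, 0], 100)
        x_aff = scale * x + shift
        assert standardized_difference(x_aff, Z) == pytest.approx(
            standardized_difference(x, Z), rel=1e-9
        )
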