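"""Propensity fitting and greedy caliper matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calipermatch import (
    caliper_width,
    fit_propensity,
    greedy_match,
    match_gamma_grid,
    DEFAULT_GAMMA_GRID,
)
from calipermatch.matching import PropensityModelError

from conftest import brute_force_match


class TestFitPropensity:
    def test_null_model_slopes_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50_000, 4))
        Z = (rng.random(50_000) < 0.3).astype(int)
        fit = fit_propensity(X, Z)
        assert fit.converged
        assert np.all(np.abs(fit.coefficients[1:]) < 0.05)

    def test_two_by_two_closed_form_slope(self):
        """Single binary covariate: the MLE slope is the log cross-product
        ratio of the 2x2 table."""
        x = np.array([1] * 30 + [0] * 20 + [1] * 20 + [0] * 30, dtype=float)
        Z = np.array([1] * 50 + [0] * 50)
        fit = fit_propensity(x[:, None], Z)
        assert fit.coefficients[1] == pytest.approx(np.log(30 * 30 / (20 * 20)), abs=1e-6)

    def test_intercept_only_logit_of_treated_fraction(self):
        x = np.empty((80, 0))  # no covariates: intercept-only model
        Z = np.array([1] * 20 + [0] * 60)
        fit = fit_propensity(x, Z)
        assert fit.intercept == pytest.approx(np.log(20 / 60), abs=1e-6)

    def test_logit_ps_consistent_with_ps(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 3))
        Z = (rng.random(500) < 0.4).astype(int)
        fit = fit_propensity(X, Z)
        np.testing.assert_allclose(
            fit.logit_ps, np.log(fit.ps / (1 - fit.ps)), atol=1e-8
        )

    def test_separation_reported_with_column(self):
        x = np.array([1.0] * 10 + [0.0] * 10)
        Z = np.array([1] * 10 + [0] * 10)
        with pytest.raises(PropensityModelError):
            fit_propensity(x[:, None], Z, column_names=["sep_col"])

    def test_empty_arm_rejected(self):
        with pytest.raises(PropensityModelError, match="non-empty"):
            fit_propensity(np.zeros((5, 1)), np.ones(5, dtype=int))


class TestCaliperWidth:
    def test_unit_variances(self):
        lp = np.concatenate([np.array([-1.0, 1.0]) , np.array([-1.0, 1.0])])
        Z = np.array([1, 1, 0, 0])
        w = caliper_width(lp, Z, 0.2)
        assert w == pytest.approx(0.2 * np.sqrt(2.0))  # both group variances 2

    def test_pooling_is_mean_of_variances(self):
        t = np.array([0.0, 2.0])  # var 2
        c = np.array([1.0, 1.0, 1.0])  # var 0
        lp = np.concatenate([t, c])
        Z = np.array([1, 1, 0, 0, 0])
        assert caliper_width(lp, Z, 1.0) == pytest.approx(1.0)

    def test_gamma_zero_exact_match_limit(self):
        lp = np.array([0.0, 1.0, 0.0, 1.0])
        Z = np.array([1, 1, 0, 0])
        assert caliper_width(lp, Z, 0.0) == 0.0

    def test_degenerate_scores_warn(self):
        lp = np.zeros(6)
        Z = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            assert caliper_width(lp, Z, 0.2) == 0.0


class TestGreedyMatch:
    def test_unique_nearest_within_caliper(self):
        lp = np.array([0.0, 0.05, 0.3])
        Z = np.array([1, 0, 0])
        ms = greedy_match(lp, Z, 0.1, order_seed=0)
        assert ms.pairs.tolist() == [[0, 1]]

    def test_outside_caliper_unmatched(self):
        lp = np.array([0.0, 0.5])
        Z = np.array([1, 0])
        ms = greedy_match(lp, Z, 0.1, order_seed=0)
        assert ms.n_pairs == 0

    @pytest.mark.parametrize("trial", range(0, 200, 1))
    def test_equals_brute_force_oracle(self, trial):
        """Fast matcher reproduces the naive quadratic matcher exactly on
        random instances (rounded scores make distance ties common)."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(10, 91))
        lp = np.round(rng.standard_normal(n), int(rng.integers(1, 4)))
        Z = np.zeros(n, dtype=int)
        Z[rng.permutation(n)[: n // 3 + 1]] = 1
        width = float(rng.random())
        ms = greedy_match(lp, Z, width, order_seed=trial)
        assert ms.pairs.tolist() == brute_force_match(lp, Z, width, trial)

    def test_matching_invariants_on_random_instance(self):
        rng = np.random.default_rng(5)
        lp = rng.standard_normal(2000)
        Z = (rng.random(2000) < 0.3).astype(int)
        w = caliper_width(lp, Z, 0.2)
        ms = greedy_match(lp, Z, w, order_seed=9)
        used = np.concatenate([ms.treated_rows, ms.control_rows])
        assert len(np.unique(used)) == used.size  # without replacement
        assert np.all(Z[ms.treated_rows] == 1)
        assert np.all(Z[ms.control_rows] == 0)
        dist = np.abs(lp[ms.treated_rows] - lp[ms.control_rows])
        assert np.all(dist <= w + 1e-12)

    def test_invariant_to_control_permutation(self):
        """Permuting control rows does not change which subjects get
        matched (same treated order, deterministic tie-breaks on distinct
        scores)."""
        rng = np.random.default_rng(6)
        nt, nc = 40, 80
        lp_t = rng.standard_normal(nt)
        lp_c = rng.standard_normal(nc)
        Z = np.array([1] * nt + [0] * nc)
        lp = np.concatenate([lp_t, lp_c])
        ms1 = greedy_match(lp, Z, 0.3, order_seed=1)
        perm = rng.permutation(nc)
        lp2 = np.concatenate([lp_t, lp_c[perm]])
        ms2 = greedy_match(lp2, Z, 0.3, order_seed=1)
        # map permuted control rows back and compare matched score pairs
        s1 = sorted((t, round(lp[c], 12)) for t, c in ms1.pairs)
        s2 = sorted((t, round(lp2[c], 12)) for t, c in ms2.pairs)
        assert s1 == s2


class TestGammaGrid:
    def test_default_grid_yields_50_samples(self):
        rng = np.random.default_rng(7)
        lp = rng.standard_normal(500)
        Z = (rng.random(500) < 0.3).astype(int)
        samples = match_gamma_grid(lp, Z, DEFAULT_GAMMA_GRID, order_seed=0)
        assert len(samples) == 50
        assert samples[0].gamma == 0.05 and samples[-1].gamma == 2.5

    def test_grid_equals_individual_runs(self):
        rng = np.random.default_rng(8)
        lp = rng.standard_normal(400)
        Z = (rng.random(400) < 0.25).astype(int)
        gammas = (0.1, 0.5, 1.5)
        grid = match_gamma_grid(lp, Z, gammas, order_seed=3)
        for g, ms in zip(gammas, grid):
            w = caliper_width(lp, Z, g)
            solo = greedy_match(lp, Z, w, order_seed=3)
            np.testing.assert_array_equal(ms.pairs, solo.pairs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pair_count_monotone_in_gamma(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        lp = rng.standard_normal(n)
        Z = (rng.random(n) < 0.35).astype(int)
        if Z.sum() in (0, n):
            return
        counts = [ms.n_pairs for ms in match_gamma_grid(lp, Z, (0.05, 0.2, 0.5, 1.0, 2.5), order_seed=0)]
        assert counts == sorted(counts)

    def test_nonbinding_caliper_matches_everyone(self):
        rng = np.random.default_rng(9)
        lp = rng.standard_normal(300)
        Z = np.zeros(300, dtype=int)
        Z[:100] = 1
        (ms,) = match_gamma_grid(lp, Z, (50.0,), order_seed=0)
        assert ms.n_pairs == 100

    def test_mean_pair_distance_nondecreasing_in_gamma(self):
        rng = np.random.default_rng(10)
        lp = rng.standard_normal(3000) * 1.2
        Z = (rng.random(3000) < 0.25).astype(int)
        grid = match_gamma_grid(lp, Z, (0.1, 0.3, 0.6, 1.2, 2.5), order_seed=4)
        means = [
            np.abs(lp[ms.treated_rows] - lp[ms.control_rows]).mean() for ms in grid
        ]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
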