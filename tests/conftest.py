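import numpy as np
import pytest

from calipermatch import default_coefficients, simulate_cohort


def brute_force_match(logit_ps, Z, width, order_seed):
    """Naive quadratic greedy matcher: reference oracle.

    Treated subjects in the seeded random order; each scans every surviving
    control for the minimum |distance| (ties to the lowest control row
    index) and pairs if within the caliper.
    """
    logit_ps = np.asarray(logit_ps, dtype=float)
    Z = np.asarray(Z)
    rng = np.random.default_rng(order_seed)
    treated = np.flatnonzero(Z == 1)
    controls = np.flatnonzero(Z == 0)
    order = rng.permutation(treated.size)
    alive = sorted(controls.tolist())
    pairs = []
    for t in treated[order]:
        best, bd = None, np.inf
        for c in alive:
            d = abs(logit_ps[t] - logit_ps[c])
            if d < bd:
                bd, best = d, c
        if best is not None and bd <= width:
            pairs.append([int(t), int(best)])
            alive.remove(best)
    return pairs


@pytest.fixture(scope="session")
def binary_cohort():
    """Moderately confounded binary-outcome cohort for unit tests
    (uncalibrated intercepts, fixed seed)."""
    coeffs = default_coefficients(
        "binary", beta=-0.1, intercept_treat=-1.34
    )
    return simulate_cohort("independent_normal", coeffs, n=4000, seed=123), coeffs


@pytest.fixture(scope="session")
def continuous_cohort():
    coeffs = default_coefficients(
        "continuous", beta=1.5, intercept_treat=-1.34
    )
    return simulate_cohort("independent_normal", coeffs, n=4000, seed=456), coeffs
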