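"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's fitting code paths: they scan
a dense lifetime grid and solve the remaining linear coefficients by
ordinary least squares, so agreement with the main fitters is a genuine
cross-check, not a tautology.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def biexp_grid_oracle(t, y, tau_fast_bounds=(10.0, 40.0),
                      tau_slow_bounds=(60.0, 3000.0), n_fast=25, n_slow=120):
    """Dense (tau_fast, tau_slow) grid search with linear LSQ amplitudes.

    Returns (a_fast, tau_fast, a_slow, tau_slow, offset, residual_norm).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = None
    for tf in np.geomspace(*tau_fast_bounds, n_fast):
        bf = np.exp(-t / tf)
        for ts in np.geomspace(*tau_slow_bounds, n_slow):
            X = np.column_stack([bf, np.exp(-t / ts), np.ones_like(t)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = float(np.linalg.norm(X @ coef - y))
            if best is None or r < best[-1]:
                best = (coef[0], tf, coef[1], ts, coef[2], r)
    return best


def i535_grid_oracle(t, y, lifetime_bounds=(5.0, 200.0), n_grid=200):
    """Lifetime grid search with linear solve for constant/amplitude/slope."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = None
    for life in np.geomspace(*lifetime_bounds, n_grid):
        X = np.column_stack([np.ones_like(t), np.exp(-t / life), t])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = float(np.linalg.norm(X @ coef - y))
        if best is None or r < best[-1]:
            best = (coef[0], coef[1], life, coef[2], r)
    return best


@pytest.fixture(scope="session")
def default_pam_trace():
    from fluctlight import QuenchingParams, simulate_pam_trace

    return simulate_pam_trace(QuenchingParams())


@pytest.fixture(scope="session")
def default_ecs_trace():
    from fluctlight import simulate_ecs_trace

    return simulate_ecs_trace()
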