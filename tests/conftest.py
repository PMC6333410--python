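"""Shared fixtures: toy network, small synthetic study, LP brute-force oracle."""

import itertools

import numpy as np
import pytest

from cellfactory.synth import (SyntheticStudyParams, make_toy_model,
                               simulate_designs)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def small_study(toy_model):
    """150-record synthetic study used by unit tests (seeded)."""
    params = SyntheticStudyParams(n_records=150, seed=7)
    records, sidecar, truth = simulate_designs(params, toy_model)
    return records, sidecar, truth


def enumerate_polytope_max(S, lb, ub, c, tol=1e-9):
    """Brute-force LP oracle: max c.v over {S v = 0, lb <= v <= ub}.

    Enumerates candidate vertices of the flux polytope by fixing every
    subset of d = n - rank(S) coordinates at a finite bound and solving the
    equality system for the rest; feasible solutions are vertices (plus
    possibly non-extreme points, which never exceed the true maximum).
    Only intended for networks with <= 6 reactions.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb, ub, c = (np.asarray(x, dtype=float) for x in (lb, ub, c))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = None
    for free_fix in itertools.combinations(range(n), d):
        for pattern in itertools.product((0, 1), repeat=d):
            v_fix = np.array([lb[j] if p == 0 else ub[j]
                              for j, p in zip(free_fix, pattern)])
            if not np.all(np.isfinite(v_fix)):
                continue
            others = [j for j in range(n) if j not in free_fix]
            A = S[:, others]
            b = -S[:, free_fix] @ v_fix
            sol, res, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            v[list(free_fix)] = v_fix
            v[others] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


@pytest.fixture(scope="session")
def lp_oracle():
    return enumerate_polytope_max
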