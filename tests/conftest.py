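"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

from vasctum import ModelParams, make_params, preset
from vasctum.model import _rhs


@pytest.fixture
def table1() -> ModelParams:
    return preset("table1_defaults")


def random_params(rng: np.random.Generator, **fixed) -> ModelParams:
    """A valid random parameter set over the study ranges.

    q1, q3 log-uniform on [1e-2, 10], V0 log-uniform on [1e-4, 5e-3];
    g, c_min, k at their baseline values unless overridden.
    """
    draw = {
        "q1": 10.0 ** rng.uniform(-2, 1),
        "q3": 10.0 ** rng.uniform(-2, 1),
        "V0": 10.0 ** rng.uniform(-4, np.log10(5e-3)),
    }
    draw.update(fixed)
    return make_params(**draw)


def brute_force_steady_states(p: ModelParams, n_grid: int = 2000):
    """Steady states found without the closed forms, as an oracle.

    SL side: with c >= c_min the death term is off, so dT/dt = 0 forces
    T = 0 (then dc/dt = 0 gives c = 1) or T = 1 - V0 (then c solves a
    linear balance, found by bisection of dc/dt over [c_min, 1]).  NL
    side: a sign-change scan of dc/dt along the starvation T-nullcline
    over (0, c_min), refined by brentq.  Returns a list of (T, c) pairs
    restricted to the admissible box.
    """
    found = [(0.0, 1.0)]
    T2 = 1.0 - p.V0

    def dc_at_T2(c):
        return _rhs(T2, c, p)[1]

    if dc_at_T2(p.c_min) >= 0.0 >= dc_at_T2(1.0):
        c2 = brentq(dc_at_T2, p.c_min, 1.0, xtol=1e-15, rtol=8.9e-16)
        found.append((T2, c2))

    def t_null(c):
        return (1.0 - p.V0) - (p.delta1 / p.q2) * (p.c_min / c - 1.0)

    def G(c):
        return _rhs(t_null(c), c, p)[1]

    grid = np.linspace(p.c_min * 1e-4, p.c_min * (1 - 1e-9), n_grid)
    vals = np.array([G(c) for c in grid])
    for i in range(n_grid - 1):
        if vals[i] * vals[i + 1] < 0:
            c = brentq(G, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16)
            T = t_null(c)
            if 0.0 <= T <= 1.0 - p.V0:
                found.append((T, c))
    return found
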