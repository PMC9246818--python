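"""Right-hand side of the dimensionless tumour/oxygen ODE system.

State variables: tumour volume fraction ``T >= 0`` and oxygen concentration
``0 <= c <= 1`` (relative to the vascular level).  The dynamics are

    dT/dt = q2 c T (1 - (T + V0)) - delta1 (c_min - c) H(c_min - c) T
    dc/dt = g (1 - c) V0 - q1 c T - q3 c T (1 - (T + V0))

with the unit step ``H(x) = 1`` for ``x >= 0``.  The death switch at
``c = c_min`` is continuous: the death term vanishes there, so the vector
field is C^0 across the switch (but not C^1).
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .params import ModelParams

__all__ = ["State", "heaviside", "rhs"]


class State(NamedTuple):
    """A point ``(T, c)`` of the phase plane."""

    T: float
    c: float


def heaviside(x: float) -> float:
    """Unit step with ``H(0) = 1``.

    The convention at zero is harmless for the dynamics because the death
    factor ``(c_min - c)`` vanishes exactly where the switch sits.
    """
    if math.isnan(x):
        raise ValueError("heaviside argument must be finite, got nan")
    return 1.0 if x >= 0 else 0.0


def _rhs(T: float, c: float, p: ModelParams) -> tuple[float, float]:
    """Unchecked RHS evaluation (hot path used by the integrator)."""
    free = 1.0 - (T + p.V0)
    growth = p.q2 * c * T * free
    gap = p.c_min - c
    death = p.delta1 * gap * T if gap >= 0 else 0.0
    dT = growth - death
    dc = p.g * (1.0 - c) * p.V0 - p.q1 * c * T - p.q3 * c * T * free
    return dT, dc


def rhs(state: State | tuple[float, float], p: ModelParams) -> tuple[float, float]:
    """Time derivatives ``(dT/dt, dc/dt)`` at ``state``.

    Raises ``ValueError`` on non-finite input.  Note the tumour-free axis
    ``T = 0`` is invariant (``dT/dt = 0`` for every ``c``) and the oxygen
    concentration is confined to ``[0, 1]``: supply is positive at ``c = 0``
    and non-positive at ``c = 1``.
    """
    T, c = state
    if not (math.isfinite(T) and math.isfinite(c)):
        raise ValueError(f"state must be finite, got (T={T!r}, c={c!r})")
    return _rhs(T, c, p)
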