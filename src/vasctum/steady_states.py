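"""Steady states of the tumour/oxygen system.

The phase plane splits at the hypoxia threshold ``c_min`` into a
nutrient-rich half (``c >= c_min``) where no cell death occurs and a
nutrient-poor half (``c < c_min``) where starvation death is active.
Steady states are classified by the half-plane they occupy:

* spatially limited (SL), ``c* >= c_min``: the tumour-free state
  SS1 = (0, 1), which always exists, and the space-filling state
  SS2 = (1 - V0, c2*) with ``c2* = V0 / (V0 + (q1/g)(1 - V0))``, admissible
  exactly when ``c2* >= c_min``, i.e. when the vasculature can cover the
  full tumour's maintenance demand:

      V0 >= 1 / ((g/q1) (1 - c_min)/c_min + 1)

* nutrient limited (NL), ``0 <= c* < c_min``: up to two states SS3/SS4
  where proliferation balances starvation death.  With the default
  coupling ``delta1 = q2`` the T-nullcline is
  ``T(c) = (1 - V0) - (c_min/c - 1)`` and eliminating ``T`` from the
  oxygen balance yields a single quadratic in ``c``:

      Y c^2 - c_min X c - q3 c_min^2 = 0,
      X = q1 - 3 q3 + (g/c_min + q3) V0,
      Y = 2 (q1 - q3) + (g + q3 - q1) V0.

  Roots with ``0 <= c < c_min`` and ``0 <= T(c) <= 1 - V0`` are admissible;
  the smaller-T solution is SS3 and the larger SS4 (``T(c)`` is strictly
  increasing on ``(0, c_min]``, so the T- and c-orderings agree).  The
  degenerate case ``Y = 0`` (equivalently ``V0 = 2(q3-q1)/(g+q3-q1)``)
  leaves a single linear root and SS4 is absent.

A state with ``c* = c_min`` exactly is classified SL: the NL regime is the
half-open band ``0 <= c < c_min``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .model import State, _rhs
from .params import ModelParams

__all__ = [
    "Regime",
    "Stability",
    "SteadyState",
    "NLQuadratic",
    "sl_admissibility_bound",
    "sl_steady_states",
    "t_nullcline",
    "c_nullcline_branches",
    "nl_steady_states",
    "all_steady_states",
]

#: Absolute slack on the admissibility boxes 0 <= T <= 1-V0, 0 <= c.
_ADM_TOL = 1e-12


class Regime(str, enum.Enum):
    SL = "SL"
    NL = "NL"


class Stability(str, enum.Enum):
    STABLE = "STABLE"
    UNSTABLE = "UNSTABLE"
    NON_HYPERBOLIC = "NON_HYPERBOLIC"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class SteadyState:
    """A fixed point annotated with identity, regime and admissibility.

    ``stability`` is UNDETERMINED until filled in by the stability module
    (see :func:`all_steady_states`).  ``edge`` flags NL roots that sit on
    the ``T = 0`` boundary within tolerance; they are reported because the
    admissibility convention ``0 <= T`` versus ``0 < T`` is ambiguous there.
    """

    identity: str  # "SS1" | "SS2" | "SS3" | "SS4"
    T: float
    c: float
    regime: Regime
    admissible: bool
    stability: Stability = Stability.UNDETERMINED
    edge: bool = False

    @property
    def state(self) -> State:
        return State(self.T, self.c)

    def residual(self, p: ModelParams) -> float:
        """Infinity norm of the vector field at the fixed point."""
        dT, dc = _rhs(self.T, self.c, p)
        return max(abs(dT), abs(dc))


@dataclass(frozen=True)
class NLQuadratic:
    """Coefficients of the NL steady-state quadratic ``a c^2 + b c + d = 0``.

    ``a = Y``, ``b = -c_min X``, ``d = -q3 c_min^2``.  ``Y = 0`` marks the
    degenerate (linear) case, which occurs exactly on the parameter surface
    ``V0 = 2(q3 - q1)/(g + q3 - q1)``.
    """

    X: float
    Y: float
    c_min: float
    q3: float
    #: magnitude scale of Y's two addends, used by the degeneracy test
    y_scale: float = 1.0
    a: float = field(init=False)
    b: float = field(init=False)
    d: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "a", self.Y)
        object.__setattr__(self, "b", -self.c_min * self.X)
        object.__setattr__(self, "d", -self.q3 * self.c_min**2)

    @classmethod
    def from_params(cls, p: ModelParams) -> "NLQuadratic":
        X = p.q1 - 3.0 * p.q3 + (p.g / p.c_min + p.q3) * p.V0
        Y = 2.0 * (p.q1 - p.q3) + (p.g + p.q3 - p.q1) * p.V0
        scale = max(abs(2.0 * (p.q1 - p.q3)), abs((p.g + p.q3 - p.q1) * p.V0), 1.0)
        return cls(X=X, Y=Y, c_min=p.c_min, q3=p.q3, y_scale=scale)

    @property
    def degenerate(self) -> bool:
        return abs(self.Y) <= 1e-12 * self.y_scale

    def roots(self) -> list[float]:
        """Real roots, degenerate case solved linearly (largest-|.| first not guaranteed)."""
        if self.degenerate:
            if self.b == 0.0:
                return []
            return [-self.d / self.b]
        disc = self.b * self.b - 4.0 * self.a * self.d
        if disc < 0.0:
            return []
        sq = math.sqrt(disc)
        # citardauq-style stable evaluation
        qq = -0.5 * (self.b + math.copysign(sq, self.b)) if self.b != 0 else 0.5 * sq
        if qq == 0.0:
            return [0.0]
        r1 = qq / self.a
        r2 = self.d / qq
        return [r1, r2]


def sl_admissibility_bound(q1: float, g: float, c_min: float) -> float:
    """Smallest vascular volume for which the space-filling state SS2 exists.

    SS2's oxygen level satisfies ``c2* >= c_min`` iff ``V0`` is at least
    ``1 / ((g/q1)(1 - c_min)/c_min + 1)``; at equality ``c2* = c_min``.
    """
    return 1.0 / ((g / q1) * (1.0 - c_min) / c_min + 1.0)


def sl_steady_states(p: ModelParams) -> list[SteadyState]:
    """The two nutrient-rich steady states SS1 and SS2.

    SS1 = (0, 1) is always admissible.  SS2 = (1 - V0, c2*) is returned
    unconditionally with its admissibility flag set by the ``c2* >= c_min``
    criterion (equality counts as admissible, SL by convention).
    """
    ss1 = SteadyState("SS1", 0.0, 1.0, Regime.SL, admissible=True)
    c2 = p.V0 / (p.V0 + (p.q1 / p.g) * (1.0 - p.V0))
    # the equality case c2* = c_min is admissible; the tolerance absorbs the
    # last-ulp rounding of the closed form at the exact existence bound
    ss2 = SteadyState("SS2", 1.0 - p.V0, c2, Regime.SL, admissible=c2 >= p.c_min - _ADM_TOL)
    return [ss1, ss2]


def t_nullcline(c: float, p: ModelParams) -> float:
    """Nonzero-T branch of the T-nullcline in the nutrient-poor band.

    ``T(c) = (1 - V0) - (delta1/q2)(c_min/c - 1)``; with the default
    coupling ``delta1 = q2`` the prefactor is 1.  At ``c = c_min`` the
    death correction vanishes and ``T = 1 - V0``.
    """
    if c <= 0:
        raise ValueError(f"t_nullcline requires c > 0, got {c!r}")
    return (1.0 - p.V0) - (p.delta1 / p.q2) * (p.c_min / c - 1.0)


def c_nullcline_branches(c: float, p: ModelParams) -> tuple[float, float] | None:
    """Both branches ``(T_minus, T_plus)`` of the c-nullcline, or None.

    Solving the oxygen balance for ``T`` at fixed ``c`` gives

        T±(c) = (q1 + q3(1-V0) ± sqrt((q1 + q3(1-V0))^2
                  - 4 q3 g V0 (1-c)/c)) / (2 q3)

    A negative discriminant means the c-nullcline does not reach that
    oxygen level; ``None`` is returned.
    """
    if not 0 < c <= 1:
        raise ValueError(f"c_nullcline_branches requires 0 < c <= 1, got {c!r}")
    s = p.q1 + p.q3 * (1.0 - p.V0)
    disc = s * s - 4.0 * p.q3 * p.g * p.V0 * (1.0 - c) / c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    return ((s - sq) / (2.0 * p.q3), (s + sq) / (2.0 * p.q3))


def _nl_candidate(c: float, p: ModelParams) -> SteadyState | None:
    """Admissibility-check a candidate NL root and wrap it, else None."""
    if not (-_ADM_TOL <= c < p.c_min - _ADM_TOL):
        return None
    T = t_nullcline(c, p) if c > 0 else math.inf
    if not (-_ADM_TOL <= T <= 1.0 - p.V0 + _ADM_TOL):
        return None
    return SteadyState(
        "SS?", max(T, 0.0), max(c, 0.0), Regime.NL, admissible=True,
        edge=abs(T) <= 1e-9,
    )


def _nl_roots_general(p: ModelParams) -> list[float]:
    """Sign-change scan + brentq for the general delta1 != q2 case.

    No closed form is attempted: the oxygen balance evaluated along the
    general T-nullcline is scanned on a fine grid over (0, c_min) and each
    bracket is refined.
    """
    from scipy.optimize import brentq

    def G(c: float) -> float:
        T = t_nullcline(c, p)
        return _rhs(T, c, p)[1]

    lo = p.c_min * 1e-6
    grid = np.linspace(lo, p.c_min * (1.0 - 1e-9), 2000)
    vals = np.array([G(c) for c in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(brentq(G, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
    return roots


def nl_steady_states(p: ModelParams) -> list[SteadyState]:
    """Admissible nutrient-limited steady states, ordered SS3 before SS4.

    With the default coupling the roots come from :class:`NLQuadratic`;
    with a decoupled ``delta1`` they are found numerically.  Roots outside
    ``0 <= c < c_min`` or with ``T`` outside ``[0, 1 - V0]`` are dropped.
    The smaller-T state is labelled SS3, the larger SS4; a single admissible
    root is always SS3 (the T-nullcline then meets only the lower branch of
    the c-nullcline).
    """
    if p.delta1_is_coupled:
        raw = NLQuadratic.from_params(p).roots()
    else:
        raw = _nl_roots_general(p)
    states = [s for c in raw if (s := _nl_candidate(c, p)) is not None]
    states.sort(key=lambda s: s.T)
    for s, name in zip(states, ("SS3", "SS4")):
        s.identity = name
    return states


def all_steady_states(p: ModelParams, annotate_stability: bool = True) -> list[SteadyState]:
    """All steady states (SS1, SS2 and any admissible NL states).

    SS1 and SS2 are always present (SS2 possibly flagged inadmissible) so
    that the existence pattern — {SS1, SS3}, {SS1, SS2, SS3, SS4} or
    {SS1, SS2} — is recoverable from the admissibility flags.  When
    ``annotate_stability`` is set, each admissible state's ``stability``
    field is filled by the linear stability analysis.
    """
    states = sl_steady_states(p) + nl_steady_states(p)
    if annotate_stability:
        from .stability import classify  # local import: stability builds on this module

        for s in states:
            if s.admissible:
                s.stability = classify(s, p).classification
    return states
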