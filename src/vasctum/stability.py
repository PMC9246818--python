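"""Linear stability of the steady states.

The vector field is smooth on each side of the death switch ``c = c_min``,
so the Jacobian is regime-dependent.  Writing ``S = 1 - T - V0`` for the
free space:

nutrient-rich side (``c > c_min``, no death term)::

    J11 = q2 c (1 - 2T - V0)        J12 = q2 T S
    J21 = -c (q1 + q3 (1 - 2T - V0))
    J22 = -g V0 - q1 T - q3 T S

nutrient-poor side (``c < c_min``) adds the death-term derivatives::

    J11 += -delta1 (c_min - c)      J12 += +delta1 T

At the switch itself the field is continuous but not differentiable; a
Jacobian there must be requested one-sided via the ``regime`` argument.

Closed forms at the SL states (each Jacobian is triangular there):

* SS1 = (0, 1):  eigenvalues ``q2 (1 - V0) > 0`` and ``-g V0 < 0`` — a
  saddle, so the tumour-free state is always unstable;
* SS2 = (1 - V0, c2*): eigenvalues ``-q2 (1 - V0) c2* < 0`` and
  ``-g V0 - q1 (1 - V0) < 0`` — always stable when admissible.

For the NL states no closed form is attempted; eigenvalues are computed
numerically.  The diagonal entries are negative at any NL steady state
(negative trace); the sign of J21 decides the determinant and hence
stability: J21 < 0 at SS3 (stable), J21 > 0 at SS4, which is observed to
be unstable across audited parameter sweeps (an audited numerical
property, not a theorem — the classifier reports whatever it finds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .steady_states import Regime, Stability, SteadyState

__all__ = ["StabilityReport", "jacobian_at", "sl_eigenvalues", "classify", "HYPERBOLICITY_TOL"]

#: eigenvalue real parts within this of zero are treated as non-hyperbolic
HYPERBOLICITY_TOL = 1e-10

#: steady states within this distance of the switch are evaluated one-sided
_SWITCH_TOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: tuple[complex, complex]
    classification: Stability
    sign_pattern: tuple[int, int, int, int]
    trace: float
    determinant: float


def jacobian_at(state, p: ModelParams, regime: Regime | None = None) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at ``state``.

    ``regime`` selects the side of the death switch; by default it is
    inferred from ``c``.  Exactly at ``c = c_min`` the field is not
    differentiable and the caller must pick a side explicitly.
    """
    T, c = state
    if regime is None:
        if c == p.c_min:
            raise ValueError(
                "the vector field is not differentiable at c = c_min; pass "
                "regime=Regime.SL or Regime.NL for a one-sided Jacobian"
            )
        regime = Regime.NL if c < p.c_min else Regime.SL
    S = 1.0 - T - p.V0
    lin = 1.0 - 2.0 * T - p.V0
    j11 = p.q2 * c * lin
    j12 = p.q2 * T * S
    j21 = -c * (p.q1 + p.q3 * lin)
    j22 = -p.g * p.V0 - p.q1 * T - p.q3 * T * S
    if regime is Regime.NL:
        j11 -= p.delta1 * (p.c_min - c)
        j12 += p.delta1 * T
    return np.array([[j11, j12], [j21, j22]])


def sl_eigenvalues(p: ModelParams, which: str) -> tuple[float, float]:
    """Closed-form eigenvalues at SS1 or SS2.

    SS2's eigenvalues are only meaningful where SS2 is admissible; an
    inadmissible SS2 raises ``ValueError``.
    """
    if which == "SS1":
        return (p.q2 * (1.0 - p.V0), -p.g * p.V0)
    if which == "SS2":
        c2 = p.V0 / (p.V0 + (p.q1 / p.g) * (1.0 - p.V0))
        if c2 < p.c_min:
            raise ValueError(
                f"SS2 is inadmissible here (c2*={c2:.6g} < c_min={p.c_min:.6g})"
            )
        return (-p.q2 * (1.0 - p.V0) * c2, -p.g * p.V0 - p.q1 * (1.0 - p.V0))
    raise ValueError(f"which must be 'SS1' or 'SS2', got {which!r}")


def _classify_eigs(eigs) -> Stability:
    re = [e.real for e in eigs]
    if all(r < -HYPERBOLICITY_TOL for r in re):
        return Stability.STABLE
    if any(r > HYPERBOLICITY_TOL for r in re):
        return Stability.UNSTABLE
    return Stability.NON_HYPERBOLIC


def classify(ss: SteadyState, p: ModelParams) -> StabilityReport:
    """Full stability report for an admissible steady state.

    SL states use the closed-form eigenvalues; NL states use the numerical
    eigenvalues of the analytic Jacobian.  States lying within 1e-9 of the
    switch are evaluated one-sided in their own regime.  A non-hyperbolic
    spectrum yields the NON_HYPERBOLIC label, never an exception.
    """
    if not ss.admissible:
        raise ValueError(f"{ss.identity} is inadmissible; stability is undefined")
    regime = ss.regime if abs(ss.c - p.c_min) <= _SWITCH_TOL else None
    J = jacobian_at(ss.state, p, regime=regime)
    if ss.identity in ("SS1", "SS2"):
        eigs = tuple(complex(e) for e in sl_eigenvalues(p, ss.identity))
    else:
        eigs = tuple(np.linalg.eigvals(J))
    signs = tuple(int(np.sign(x)) for x in J.ravel())
    return StabilityReport(
        jacobian=J,
        eigenvalues=eigs,
        classification=_classify_eigs(eigs),
        sign_pattern=signs,
        trace=float(J[0, 0] + J[1, 1]),
        determinant=float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]),
    )
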