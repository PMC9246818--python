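"""Growth-regime classification, parameter-space scans and bifurcation diagrams.

A parameter point is classified by which non-trivial stable steady states
it supports (the tumour-free state SS1 is always an unstable saddle and
never attracts):

* SL — only the space-filling state SS2 is stable: every growing tumour
  arrests by running out of space;
* NL — only the hypoxic state SS3 is stable: arrest happens when
  proliferation balances starvation death;
* BISTABLE — SS2 and SS3 are both stable and the attained state depends
  on the initial condition.

Classification is by steady-state admissibility + linear stability, not by
simulation: it is deterministic, fast and matches the definition of the
regimes; simulation serves as an independent audit.  Grid scans are pure
per-node computations, so the output is identical regardless of
evaluation order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, make_params
from .steady_states import (
    Stability,
    SteadyState,
    all_steady_states,
    c_nullcline_branches,
    t_nullcline,
)

__all__ = [
    "GrowthRegime",
    "RegimeLabel",
    "AnomalyError",
    "classify_regime",
    "scan_regime_map",
    "BifurcationBranch",
    "bifurcation_diagram",
    "bistable_window",
    "nullclines",
]


class GrowthRegime(str, enum.Enum):
    SL = "SL"
    NL = "NL"
    BISTABLE = "BISTABLE"


class AnomalyError(RuntimeError):
    """No stable non-trivial steady state exists at a parameter point.

    This would mean a coverage gap of the three-regime picture; it is
    surfaced loudly instead of guessing a label.
    """


@dataclass(frozen=True)
class RegimeLabel:
    label: GrowthRegime
    admissible_stable_states: frozenset[str]


def _admissibility_pattern(states: Sequence[SteadyState]) -> str:
    return "+".join(s.identity for s in states if s.admissible)


def classify_regime(p: ModelParams) -> RegimeLabel:
    """Classify a parameter point into SL, NL or BISTABLE."""
    states = all_steady_states(p)
    stable = frozenset(
        s.identity
        for s in states
        if s.admissible and s.identity != "SS1" and s.stability is Stability.STABLE
    )
    nontrivial = stable & {"SS2", "SS3"}
    if nontrivial == {"SS2"}:
        return RegimeLabel(GrowthRegime.SL, nontrivial)
    if nontrivial == {"SS3"}:
        return RegimeLabel(GrowthRegime.NL, nontrivial)
    if nontrivial == {"SS2", "SS3"}:
        return RegimeLabel(GrowthRegime.BISTABLE, nontrivial)
    raise AnomalyError(
        f"no stable non-trivial steady state at {p!r}; stable set: {sorted(stable)}"
    )


def scan_regime_map(
    q1: float,
    g: float,
    c_min: float,
    V0_grid: Sequence[float],
    q3_grid: Sequence[float],
    k: float = 1e-2,
) -> pd.DataFrame:
    """Regime label and admissibility pattern on a (V0, q3) grid.

    Returns a DataFrame with columns ``V0, q3, label, pattern`` sorted by
    (V0, q3).  Region boundaries are recoverable as label changes between
    neighbouring nodes.
    """
    V0_grid = np.asarray(V0_grid, dtype=float)
    q3_grid = np.asarray(q3_grid, dtype=float)
    for name, grid, upper in (("V0_grid", V0_grid, 1.0), ("q3_grid", q3_grid, np.inf)):
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
        if grid[0] <= 0 or grid[-1] >= upper:
            raise ValueError(f"{name} out of admissible range")
    rows = []
    for V0 in V0_grid:
        for q3 in q3_grid:
            p = make_params(q1=q1, q3=float(q3), V0=float(V0), g=g, c_min=c_min, k=k)
            states = all_steady_states(p)
            label = classify_regime(p)
            rows.append(
                {
                    "V0": float(V0),
                    "q3": float(q3),
                    "label": label.label.value,
                    "pattern": _admissibility_pattern(states),
                }
            )
    return pd.DataFrame(rows).sort_values(["V0", "q3"], kind="mergesort").reset_index(drop=True)


@dataclass
class BifurcationBranch:
    """One steady-state branch traced over the vascular volume.

    ``points`` rows are (V0, T_star, stable) ordered by V0.  The SS2
    branch satisfies ``T_star = 1 - V0`` wherever present.
    """

    identity: str
    points: pd.DataFrame  # columns V0, T, c, stable


def bifurcation_diagram(
    q1: float,
    q3: float,
    g: float = 5.0,
    c_min: float = 1e-2,
    V0_range: tuple[float, float] = (1e-4, 5e-3),
    n_points: int = 200,
    k: float = 1e-2,
    log_spacing: bool = True,
) -> list[BifurcationBranch]:
    """Steady-state branches of T* versus V0 at fixed (q1, q3).

    Branch assembly is per identity with no continuation machinery — the
    closed forms and the quadratic make every node exact on its own.
    """
    lo, hi = V0_range
    if not 0 < lo < hi < 1:
        raise ValueError(f"V0_range must satisfy 0 < lo < hi < 1, got {V0_range!r}")
    if log_spacing:
        grid = np.geomspace(lo, hi, n_points)
    else:
        grid = np.linspace(lo, hi, n_points)
    per_identity: dict[str, list[dict]] = {}
    for V0 in grid:
        p = make_params(q1=q1, q3=q3, V0=float(V0), g=g, c_min=c_min, k=k)
        for s in all_steady_states(p):
            if not s.admissible or s.identity == "SS1":
                continue
            per_identity.setdefault(s.identity, []).append(
                {
                    "V0": float(V0),
                    "T": s.T,
                    "c": s.c,
                    "stable": s.stability is Stability.STABLE,
                }
            )
    return [
        BifurcationBranch(identity=ident, points=pd.DataFrame(rows))
        for ident, rows in sorted(per_identity.items())
    ]


def bistable_window(branches: list[BifurcationBranch]) -> tuple[float, float] | None:
    """V0 interval where stable SS2 and stable SS3 coexist, or None.

    Endpoints are the extreme grid nodes at which both branches are
    present and stable (empirical, at grid resolution).
    """
    by_id = {b.identity: b.points for b in branches}
    if "SS2" not in by_id or "SS3" not in by_id:
        return None
    s2 = set(by_id["SS2"].loc[by_id["SS2"]["stable"], "V0"])
    s3 = set(by_id["SS3"].loc[by_id["SS3"]["stable"], "V0"])
    both = sorted(s2 & s3)
    if not both:
        return None
    return (both[0], both[-1])


def nullclines(p: ModelParams, c_grid: Sequence[float]) -> pd.DataFrame:
    """Sampled nullcline curves for phase-portrait construction.

    Returns a DataFrame with columns ``c, T_nullcline, c_nullcline_minus,
    c_nullcline_plus``; NaN marks domain gaps (the T-nullcline's nonzero
    branch only exists in the nutrient-poor band, the c-nullcline only
    where its discriminant is non-negative).  The trivial nullclines T = 0
    and the branch point where T- and T+ merge are implicit in the data.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0) or np.any(c_grid > 1):
        raise ValueError("c_grid must lie in (0, 1]")
    rows = []
    for c in c_grid:
        row = {"c": float(c), "T_nullcline": np.nan,
               "c_nullcline_minus": np.nan, "c_nullcline_plus": np.nan}
        if c < p.c_min:
            row["T_nullcline"] = t_nullcline(float(c), p)
        branches = c_nullcline_branches(float(c), p)
        if branches is not None:
            row["c_nullcline_minus"], row["c_nullcline_plus"] = branches
        rows.append(row)
    return pd.DataFrame(rows)
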