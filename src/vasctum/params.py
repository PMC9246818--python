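"""Parameter containers for the vascular tumour growth model.

The model couples the tumour volume fraction ``T`` and the oxygen
concentration ``c`` inside a tissue of fixed total volume that is shared
between tumour cells and a static vascular compartment of volume fraction
``V0``.  Two parameterisations are supported:

* :class:`DimensionalParams` — rate constants carrying physical units,
  together with the total space ``S_max``, the vascular oxygen level
  ``c_max_star`` and a time scale ``tau``;
* :class:`ModelParams` — the dimensionless parameter vector obtained by
  rescaling space by ``S_max``, oxygen by ``c_max_star`` and time by
  ``tau`` (see :func:`nondimensionalise`).

Two structural constraints are enforced eagerly, at construction time,
because every downstream analysis relies on them:

* the proliferation oxygen demand is tied to the proliferation rate by the
  conversion factor ``k``: ``q2 = q3 / k``;
* the starvation death rate ``delta1`` equals the proliferation rate
  ``q2``.  This coupling reflects the empirical correlation between tumour
  proliferation and death rates; a general ``delta1`` is accepted only when
  the explicit ``allow_general_delta1`` flag is set, and the closed forms
  that assume the coupling then fall back to general formulas downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = [
    "ParameterError",
    "DimensionalParams",
    "ModelParams",
    "nondimensionalise",
    "make_params",
    "preset",
    "PRESETS",
]

#: Relative tolerance for the structural identities q2 = q3/k and delta1 = q2.
_REL_TOL = 1e-12


class ParameterError(ValueError):
    """A parameter set violates one of the model's structural constraints."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (isinstance(value, (int, float)) and value > 0 and value == value):
            raise ParameterError(name, f"must be a strictly positive finite number, got {value!r}")


def _close(a: float, b: float, rtol: float = _REL_TOL) -> bool:
    return abs(a - b) <= rtol * max(abs(a), abs(b))


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional rate constants of the tumour/oxygen system.

    Attributes
    ----------
    q1_star : float
        Oxygen consumption rate for cell maintenance (per conc per time).
    q2_star : float
        Proliferation rate constant.
    q3_star : float
        Oxygen consumption rate for proliferation; tied to ``q2_star`` by
        the conversion factor: ``q3_star = q2_star / k_star``.
    delta1_star : float
        Starvation death rate constant.
    g_star : float
        Oxygen exchange rate per unit vascular volume.
    c_min_star : float
        Severe-hypoxia oxygen threshold; must satisfy
        ``0 < c_min_star < c_max_star``.
    c_max_star : float
        Oxygen concentration in the vasculature (the supply saturates there).
    S_max : float
        Total physical space available to tumour and vasculature.
    V0_star : float
        Constant vascular volume, ``0 < V0_star < S_max``.
    k_star : float
        Conversion factor between proliferation and its oxygen demand.
    tau : float
        Time scale used by the non-dimensionalisation.
    """

    q1_star: float
    q2_star: float
    q3_star: float
    delta1_star: float
    g_star: float
    c_min_star: float
    c_max_star: float
    S_max: float
    V0_star: float
    k_star: float
    tau: float

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])
        if not self.c_min_star < self.c_max_star:
            raise ParameterError(
                "c_min_star",
                f"hypoxia threshold {self.c_min_star} must lie below the vascular "
                f"oxygen level c_max_star={self.c_max_star}",
            )
        if not self.V0_star < self.S_max:
            raise ParameterError(
                "V0_star",
                f"vascular volume {self.V0_star} must be smaller than the total space "
                f"S_max={self.S_max}",
            )
        if not _close(self.q3_star, self.q2_star / self.k_star):
            raise ParameterError(
                "q3_star",
                f"must equal q2_star/k_star = {self.q2_star / self.k_star!r} "
                f"(got {self.q3_star!r})",
            )


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter vector of the rescaled system.

    ``T`` and ``V0`` are volume fractions of the total space, ``c`` is the
    oxygen concentration relative to the vascular level, so ``0 < c_min < 1``
    and ``0 < V0 < 1``.  The identities ``q2 = q3/k`` and (by default)
    ``delta1 = q2`` are enforced to machine precision.
    """

    q1: float
    q2: float
    q3: float
    delta1: float
    g: float
    c_min: float
    V0: float
    k: float
    allow_general_delta1: bool = False

    def __post_init__(self):
        _require_positive(self, ["q1", "q2", "q3", "delta1", "g", "c_min", "V0", "k"])
        if not self.c_min < 1:
            raise ParameterError("c_min", f"must lie in (0, 1), got {self.c_min!r}")
        if not self.V0 < 1:
            raise ParameterError("V0", f"must lie in (0, 1), got {self.V0!r}")
        if not _close(self.q2, self.q3 / self.k):
            raise ParameterError(
                "q2", f"must equal q3/k = {self.q3 / self.k!r} (got {self.q2!r})"
            )
        if not self.allow_general_delta1 and not _close(self.delta1, self.q2):
            raise ParameterError(
                "delta1",
                f"defaults to the proliferation rate q2 = {self.q2!r} (got "
                f"{self.delta1!r}); pass allow_general_delta1=True to decouple them",
            )

    @property
    def delta1_is_coupled(self) -> bool:
        """True when ``delta1 = q2`` holds, enabling the closed-form T-nullcline."""
        return _close(self.delta1, self.q2)

    def with_V0(self, V0: float) -> "ModelParams":
        """Copy of this parameter set with a different vascular volume."""
        return replace(self, V0=V0)


def nondimensionalise(p: DimensionalParams) -> ModelParams:
    """Map dimensional parameters onto the dimensionless vector.

    Space is scaled by ``S_max``, oxygen by ``c_max_star`` and time by
    ``tau``::

        V0  = V0_star / S_max          q1 = q1_star S_max / tau
        q3  = q3_star S_max^2 / tau    q2 = q2_star S_max c_max_star / tau
        c_min = c_min_star / c_max_star
        delta1 = delta1_star c_max_star / tau
        g   = g_star S_max / tau

    The dimensionless conversion factor is defined as the ratio the model
    structure dictates, ``k = q3 / q2 = S_max / (c_max_star k_star)``, so
    the returned set satisfies ``q2 = q3 / k`` identically.
    """
    return ModelParams(
        q1=p.q1_star * p.S_max / p.tau,
        q2=p.q2_star * p.S_max * p.c_max_star / p.tau,
        q3=p.q3_star * p.S_max**2 / p.tau,
        delta1=p.delta1_star * p.c_max_star / p.tau,
        g=p.g_star * p.S_max / p.tau,
        c_min=p.c_min_star / p.c_max_star,
        V0=p.V0_star / p.S_max,
        k=p.S_max / (p.c_max_star * p.k_star),
        allow_general_delta1=True,  # coupling of the dimensional inputs decides
    )


def make_params(
    q1: float,
    q3: float,
    V0: float,
    *,
    g: float = 5.0,
    c_min: float = 1e-2,
    k: float = 1e-2,
    delta1: float | None = None,
    allow_general_delta1: bool = False,
) -> ModelParams:
    """Build a :class:`ModelParams` from the free parameters.

    ``q2`` is derived as ``q3 / k`` and ``delta1`` defaults to ``q2``.
    The keyword defaults are the baseline used throughout the analyses:
    oxygen exchange rate ``g = 5``, anoxic threshold ``c_min = 1e-2`` and
    conversion factor ``k = 1e-2``.
    """
    q2 = q3 / k
    if delta1 is None:
        delta1 = q2
    return ModelParams(
        q1=q1, q2=q2, q3=q3, delta1=delta1, g=g, c_min=c_min, V0=V0, k=k,
        allow_general_delta1=allow_general_delta1,
    )


#: Named benchmark parameter sets (free parameters only; g, c_min, k take the
#: baseline values of :func:`make_params` unless overridden).
PRESETS: dict[str, dict[str, float]] = {
    "table1_defaults": {"q1": 0.1, "q3": 1.0, "V0": 0.005},
    "fig1a": {"q1": 0.1, "q3": 1.0, "V0": 0.005},
    "fig1c": {"q1": 0.5, "q3": 5.0, "V0": 0.005},
    "fig1e": {"q1": 1.0, "q3": 10.0, "V0": 0.005},
    "fig3a": {"q1": 0.5, "q3": 5.0, "V0": 0.0005},
    "fig3b": {"q1": 0.5, "q3": 5.0, "V0": 0.0015},
    "fig5_A": {"q1": 0.1, "q3": 0.15, "V0": 0.005},
    "fig5_B": {"q1": 0.1, "q3": 0.8, "V0": 0.014},
    "fig5_C": {"q1": 0.1, "q3": 0.5, "V0": 0.035},
    "fig6_NL": {"q1": 1.0, "q3": 1.0, "V0": 0.0022},
    "fig6_BI": {"q1": 1.0, "q3": 5.0, "V0": 0.0022},
    "fig6_SL": {"q1": 1.0, "q3": 9.0, "V0": 0.0045},
}


def preset(name: str, **overrides) -> ModelParams:
    """Resolve a named benchmark parameter set.

    Keyword overrides replace individual entries (e.g. ``V0=0.001`` to move
    along a growth-curve family).  Unknown names raise ``KeyError`` listing
    the available presets.
    """
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    base.update(overrides)
    return make_params(**base)
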