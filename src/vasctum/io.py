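"""Configuration loading and tabular/JSON writers.

Parameter sets load from named presets or from flat key -> number mappings
(YAML or JSON).  Every run writes its numeric output as CSV (gridded or
sequence data) or JSON (structured reports) at full double precision with
deterministic column order, plus a JSON metadata sidecar carrying the
fully resolved configuration, so identical configs produce identical
outputs byte for byte (timestamps excluded by design: none are written).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams, ParameterError, PRESETS, make_params, preset
from .regimes import BifurcationBranch
from .simulate import Trajectory
from .steady_states import SteadyState
from .treatment import DoseResponsePath

__all__ = [
    "load_params",
    "params_to_dict",
    "write_metadata",
    "write_trajectory",
    "write_steady_states",
    "write_regime_map",
    "write_bifurcation",
    "write_nullclines",
    "write_sweep",
]

#: keys accepted in a parameter config file
_PARAM_KEYS = {"q1", "q2", "q3", "V0", "g", "c_min", "k", "delta1", "allow_general_delta1"}
_REQUIRED_KEYS = {"q1", "q3", "V0"}


def load_params(source: str | Path | Mapping[str, Any], **overrides) -> ModelParams:
    """Resolve a parameter set from a preset name, a file or a mapping.

    Files must contain a flat key -> number mapping (YAML or JSON) with at
    least ``q1``, ``q3`` and ``V0``; ``g``, ``c_min``, ``k`` default to the
    baseline values.  Unknown keys are rejected by name.  A ``q2`` given
    alongside ``q3`` and ``k`` must satisfy ``q2 = q3/k``.
    """
    if isinstance(source, str) and source in PRESETS:
        return preset(source, **overrides)
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a preset ({', '.join(sorted(PRESETS))}) "
                f"nor an existing file"
            )
        mapping = yaml.safe_load(path.read_text())
        if not isinstance(mapping, dict):
            raise ParameterError("<config>", f"{path} must contain a flat mapping")
    mapping.update(overrides)
    unknown = set(mapping) - _PARAM_KEYS
    if unknown:
        raise ParameterError(
            ", ".join(sorted(unknown)),
            f"unknown parameter key(s); accepted: {', '.join(sorted(_PARAM_KEYS))}",
        )
    missing = _REQUIRED_KEYS - set(mapping)
    if missing:
        raise ParameterError(", ".join(sorted(missing)), "required key(s) missing")
    q2 = mapping.pop("q2", None)
    p = make_params(**mapping)
    if q2 is not None and abs(q2 - p.q2) > 1e-12 * max(abs(q2), abs(p.q2)):
        raise ParameterError(
            "q2", f"conflicts with q3/k = {p.q2!r} (got {q2!r})"
        )
    return p


def params_to_dict(p: ModelParams) -> dict[str, float]:
    """Flat dict representation, round-trippable through :func:`load_params`."""
    d = dataclasses.asdict(p)
    if not p.allow_general_delta1:
        d.pop("allow_general_delta1")
    return d


def _dump_json(obj, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_metadata(path: str | Path, command: str, p: ModelParams | None, options: dict) -> None:
    """JSON sidecar with the fully resolved run configuration."""
    record = {
        "command": command,
        "params": None if p is None else params_to_dict(p),
        "options": options,
        "version": __version__,
    }
    _dump_json(record, Path(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory CSV with columns time, T, c at full double precision."""
    df = pd.DataFrame({"time": traj.times, "T": traj.T, "c": traj.c})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def _steady_state_record(s: SteadyState) -> dict:
    return {
        "identity": s.identity,
        "T": s.T,
        "c": s.c,
        "regime": s.regime.value,
        "admissible": s.admissible,
        "stability": s.stability.value,
    }


def write_steady_states(states: list[SteadyState], path: str | Path) -> None:
    """JSON array of steady-state records, SS1..SS4 order."""
    records = sorted((_steady_state_record(s) for s in states), key=lambda r: r["identity"])
    _dump_json(records, Path(path))


def write_regime_map(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def write_bifurcation(branches: list[BifurcationBranch], path: str | Path) -> None:
    """Branch CSV with columns identity, V0, T, c, stable."""
    frames = []
    for b in branches:
        df = b.points.copy()
        df.insert(0, "identity", b.identity)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["identity", "V0", "T", "c", "stable"]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.17g")


def write_nullclines(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def write_sweep(path_obj: DoseResponsePath, path: str | Path) -> None:
    """Sweep CSV with columns step, V, steady_T, branch, regime, jumped."""
    n = path_obj.V_values.size
    jumped = np.zeros(n, dtype=bool)
    jumped[path_obj.jump_indices] = True
    df = pd.DataFrame(
        {
            "step": np.arange(n),
            "V": path_obj.V_values,
            "steady_T": path_obj.steady_T,
            "branch": path_obj.branch,
            "regime": [r.value for r in path_obj.regime_at_step],
            "jumped": jumped,
        }
    )
    if path_obj.doses is not None:
        df.insert(1, "dose", path_obj.doses)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
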