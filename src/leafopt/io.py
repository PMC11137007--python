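"""Configuration parsing and result export.

Configuration files are YAML with three sections::

    rates:
      p:   {family: constant, level: 1.0}
      h:   {family: exp_cosine, a1: 0.0, b1: 1.0, scale: 1.0, sign: -1}
      b:   {family: constant, level: 2.0}
      u:   0.0001
    season:
      T: 1.0
      L0: 1.0
      s_max: 0.132       # optional; defaults to a non-binding bound
      n_steps: 20000
    solver:              # optional section
      integrator: fixed_rk4
      control_tol: 1.0e-8

Unknown keys anywhere are rejected with the offending key path.
Trajectories are exported as tab-separated text at full float precision, so
a round-trip through the file reproduces the arrays bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Optional, Tuple, Union

import numpy as np
import yaml

from .exceptions import ConfigError, DomainError
from .model import RateFunction, RateSet, SeasonParams, Trajectory
from .scenarios import Scenario, nonbinding_smax
from .solver import SolverSettings, evaluate_objective

__all__ = [
    "load_config",
    "save_config",
    "scenario_to_config",
    "export_trajectory",
    "read_trajectory",
]

log = logging.getLogger(__name__)

_TRAJ_COLUMNS = ("t", "L", "lambda", "s", "p", "h", "b", "hamiltonian")

_RATE_KEYS = {
    "constant": {"family", "level"},
    "exp_cosine": {"family", "a1", "b1", "scale", "sign"},
}


def _require_mapping(obj: Any, path: str) -> Dict[str, Any]:
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _require_number(obj: Any, path: str) -> float:
    if isinstance(obj, bool) or not isinstance(obj, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {obj!r}")
    return float(obj)


def _parse_rate(section: Any, path: str, period: float) -> RateFunction:
    mapping = _require_mapping(section, path)
    family = mapping.get("family")
    if family not in _RATE_KEYS:
        raise ConfigError(
            f"{path}.family: expected 'constant' or 'exp_cosine', got {family!r}"
        )
    unknown = set(mapping) - _RATE_KEYS[family]
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        if family == "constant":
            if "level" not in mapping:
                raise ConfigError(f"{path}.level: missing")
            return RateFunction.constant(
                _require_number(mapping["level"], f"{path}.level"), period=period
            )
        if "b1" not in mapping:
            raise ConfigError(f"{path}.b1: missing")
        sign = mapping.get("sign", -1)
        if sign not in (-1, 1):
            raise ConfigError(f"{path}.sign: must be -1 or 1, got {sign!r}")
        return RateFunction.exp_cosine(
            a1=_require_number(mapping.get("a1", 0.0), f"{path}.a1"),
            b1=_require_number(mapping["b1"], f"{path}.b1"),
            scale=_require_number(mapping.get("scale", 1.0), f"{path}.scale"),
            sign=int(sign),
            period=period,
        )
    except DomainError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(
    path: Union[str, Path],
) -> Tuple[RateSet, SeasonParams, SolverSettings]:
    """Parse and validate a scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    raw = _require_mapping(raw, str(path))
    unknown = set(raw) - {"rates", "season", "solver"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    season = _require_mapping(raw.get("season", {}), "season")
    unknown = set(season) - {"T", "L0", "s_max", "n_steps"}
    if unknown:
        raise ConfigError(f"season: unknown key(s) {sorted(unknown)}")
    T = _require_number(season.get("T", 1.0), "season.T")
    if T <= 0:
        raise ConfigError("season.T: must be positive")

    rates_raw = _require_mapping(raw.get("rates", {}), "rates")
    unknown = set(rates_raw) - {"p", "h", "b", "u"}
    if unknown:
        raise ConfigError(f"rates: unknown key(s) {sorted(unknown)}")
    for key in ("p", "h", "b"):
        if key not in rates_raw:
            raise ConfigError(f"rates.{key}: missing")
    u = _require_number(rates_raw.get("u", 0.0), "rates.u")
    if u < 0:
        raise ConfigError("rates.u: must be non-negative")
    try:
        rates = RateSet(
            p=_parse_rate(rates_raw["p"], "rates.p", T),
            h=_parse_rate(rates_raw["h"], "rates.h", T),
            b_eff=_parse_rate(rates_raw["b"], "rates.b", T),
            u=u,
        )
    except DomainError as exc:
        raise ConfigError(f"rates: {exc}") from exc

    try:
        L0 = _require_number(season.get("L0", 1.0), "season.L0")
        n_steps = season.get("n_steps", 20_000)
        if not isinstance(n_steps, int) or isinstance(n_steps, bool):
            raise ConfigError(f"season.n_steps: expected an integer, got {n_steps!r}")
        if "s_max" in season:
            s_max = _require_number(season["s_max"], "season.s_max")
        else:
            s_max = nonbinding_smax(rates, T=T, L0=L0)
            log.warning(
                "season.s_max not given; defaulting to the non-binding bound "
                "%.6g", s_max,
            )
        params = SeasonParams(T=T, L0=L0, s_max=s_max, n_steps=n_steps)
    except DomainError as exc:
        raise ConfigError(f"season: {exc}") from exc

    solver_raw = _require_mapping(raw.get("solver", {}), "solver")
    unknown = set(solver_raw) - {
        "integrator", "n_steps", "abs_tol", "rel_tol", "control_tol"
    }
    if unknown:
        raise ConfigError(f"solver: unknown key(s) {sorted(unknown)}")
    try:
        settings = SolverSettings(
            integrator=solver_raw.get("integrator", "fixed_rk4"),
            n_steps=solver_raw.get("n_steps"),
            abs_tol=solver_raw.get("abs_tol", 1e-10),
            rel_tol=solver_raw.get("rel_tol", 1e-8),
            control_tol=solver_raw.get("control_tol", 1e-8),
        )
    except DomainError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    return rates, params, settings


def _rate_to_dict(rate: RateFunction) -> Dict[str, Any]:
    if rate.family == "constant":
        return {"family": "constant", "level": rate.level}
    return {
        "family": "exp_cosine",
        "a1": rate.a1,
        "b1": rate.b1,
        "scale": rate.scale,
        "sign": rate.sign,
    }


def scenario_to_config(scenario: Scenario) -> Dict[str, Any]:
    """Configuration mapping that round-trips the scenario losslessly."""
    return {
        "rates": {
            "p": _rate_to_dict(scenario.rates.p),
            "h": _rate_to_dict(scenario.rates.h),
            "b": _rate_to_dict(scenario.rates.b_eff),
            "u": scenario.rates.u,
        },
        "season": {
            "T": scenario.params.T,
            "L0": scenario.params.L0,
            "s_max": scenario.params.s_max,
            "n_steps": scenario.params.n_steps,
        },
    }


def save_config(config: Dict[str, Any], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def export_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write the trajectory as a tab-separated table, one row per grid node."""
    data = np.column_stack([
        traj.t, traj.L, traj.lam, traj.s,
        traj.p_vals, traj.h_vals, traj.b_vals, traj.H_vals,
    ])
    try:
        np.savetxt(
            path, data, fmt="%.17g", delimiter="\t",
            header="\t".join(_TRAJ_COLUMNS), comments="",
        )
    except OSError as exc:
        raise IOError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory(
    path: Union[str, Path],
    rates: Optional[RateSet] = None,
    s_max: Optional[float] = None,
) -> Trajectory:
    """Read a trajectory table back; re-validates control bounds when
    ``s_max`` is supplied."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    if tuple(header) != _TRAJ_COLUMNS:
        raise IOError(f"{path}: unexpected columns {header}")
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    t, L, lam, s, p_vals, h_vals, b_vals, H_vals = data.T
    bound = s_max if s_max is not None else float(np.max(s))
    tol = 1e-9 * max(bound, 1.0)
    if np.any(s < -tol) or np.any(s > bound + tol):
        raise DomainError(f"{path}: column s violates [0, {bound}]")
    if rates is not None:
        phi = evaluate_objective(t, L, s, rates)
    else:
        phi = float(np.trapezoid((p_vals - s) * L, t))
    return Trajectory(
        t=t, L=L, lam=lam, s=s,
        p_vals=p_vals, h_vals=h_vals, b_vals=b_vals, H_vals=H_vals,
        phi=phi, s_max=bound,
    )
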