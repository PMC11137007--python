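"""Built-in scenario registry for the published figure reproductions.

Each scenario bundles a :class:`RateSet` and :class:`SeasonParams`:

* ``fig2`` — all rates constant (p=1, h=2, b=2, u=1e-4, T=1, s_max=0.132):
  three-phase schedule max -> interior -> zero.
* ``fig3`` — hazard peaks at midsummer (exp-cosine, a1=0, b1=1),
  s_max=0.155.
* ``fig4`` — hazard exp-cosine sweep over shape factor b1 in {1, 2, 4};
  the caption prints no s_max, so a non-binding bound is computed
  (10x the unconstrained seasonal maximum of s).
* ``fig5a`` — photosynthesis peaks at midsummer (exp-cosine, a1=0, b1=0.5),
  hazard constant; spring production peak.
* ``fig5b`` — effectiveness drops at midsummer
  (0.5*exp[a1 + b1*cos(2*pi*t/T)], a1=0, b1=0.5); spring production peak and
  no production in the second half of the season.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import DomainError
from .model import RateFunction, RateSet, SeasonParams
from .solver import SolverSettings, solve

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "get_scenario",
    "nonbinding_smax",
    "FIG4_B1_SWEEP",
]

FIG4_B1_SWEEP: Tuple[float, ...] = (1.0, 2.0, 4.0)

SCENARIO_NAMES = ("fig2", "fig3", "fig4", "fig5a", "fig5b")

_U = 1e-4
_T = 1.0


@dataclass(frozen=True)
class Scenario:
    name: str
    rates: RateSet
    params: SeasonParams
    description: str = ""
    sweep_axis: Optional[str] = None
    sweep_values: Tuple[float, ...] = ()


def nonbinding_smax(
    rates: RateSet,
    T: float = 1.0,
    L0: float = 1.0,
    n_steps: int = 2000,
) -> float:
    """A production bound large enough never to bind.

    Solves the problem coarsely with an effectively unbounded control and
    returns ten times the seasonal maximum of the unconstrained schedule
    (at least 1.0).  The seasonal maximum is used rather than s(0) because
    peaked hazards move the largest production away from t=0.
    """
    probe = SeasonParams(T=T, L0=L0, s_max=1e6, n_steps=n_steps)
    traj = solve(rates, probe, SolverSettings(n_steps=n_steps))
    s_peak = float(np.max(traj.s))
    if s_peak <= 0.0:
        return 1.0
    return max(1.0, 10.0 * s_peak)


def _constant_rates(p: float, h: float, b: float, u: float = _U) -> RateSet:
    return RateSet(
        p=RateFunction.constant(p, period=_T),
        h=RateFunction.constant(h, period=_T),
        b_eff=RateFunction.constant(b, period=_T),
        u=u,
    )


@lru_cache(maxsize=None)
def _build(name: str, b1: float) -> Scenario:
    if name == "fig2":
        return Scenario(
            name="fig2",
            rates=_constant_rates(p=1.0, h=2.0, b=2.0),
            params=SeasonParams(T=_T, L0=1.0, s_max=0.132),
            description="all rates constant; three-phase schedule",
        )
    if name == "fig3":
        rates = RateSet(
            p=RateFunction.constant(1.0, period=_T),
            h=RateFunction.exp_cosine(a1=0.0, b1=1.0, sign=-1, period=_T),
            b_eff=RateFunction.constant(2.0, period=_T),
            u=_U,
        )
        return Scenario(
            name="fig3",
            rates=rates,
            params=SeasonParams(T=_T, L0=1.0, s_max=0.155),
            description="hazard peaks at midsummer (b1=1)",
        )
    if name == "fig4":
        rates = RateSet(
            p=RateFunction.constant(1.0, period=_T),
            h=RateFunction.exp_cosine(a1=0.0, b1=b1, sign=-1, period=_T),
            b_eff=RateFunction.constant(2.0, period=_T),
            u=_U,
        )
        s_max = nonbinding_smax(rates, T=_T)
        return Scenario(
            name="fig4",
            rates=rates,
            params=SeasonParams(T=_T, L0=1.0, s_max=s_max),
            description=f"hazard exp-cosine, shape factor b1={b1:g}; "
                        "non-binding s_max",
            sweep_axis="b1",
            sweep_values=FIG4_B1_SWEEP,
        )
    if name == "fig5a":
        rates = RateSet(
            p=RateFunction.exp_cosine(a1=0.0, b1=0.5, sign=-1, period=_T),
            h=RateFunction.constant(2.0, period=_T),
            b_eff=RateFunction.constant(2.0, period=_T),
            u=_U,
        )
        s_max = nonbinding_smax(rates, T=_T)
        return Scenario(
            name="fig5a",
            rates=rates,
            params=SeasonParams(T=_T, L0=1.0, s_max=s_max),
            description="photosynthesis peaks at midsummer; spring "
                        "production peak",
        )
    if name == "fig5b":
        rates = RateSet(
            p=RateFunction.constant(1.0, period=_T),
            h=RateFunction.constant(2.0, period=_T),
            # seasonal modulation 0.5*exp[0.5*cos] applied to the baseline
            # effectiveness b=2, i.e. b(t) = exp[0.5*cos(2*pi*t/T)]; the
            # un-scaled modulation alone makes production unprofitable
            # everywhere (p*b*h < u+h for all t) and yields s == 0
            b_eff=RateFunction.exp_cosine(
                a1=0.0, b1=0.5, scale=1.0, sign=+1, period=_T
            ),
            u=_U,
        )
        s_max = nonbinding_smax(rates, T=_T)
        return Scenario(
            name="fig5b",
            rates=rates,
            params=SeasonParams(T=_T, L0=1.0, s_max=s_max),
            description="effectiveness drops at midsummer; spring peak, "
                        "no production late in the season",
        )
    raise DomainError(
        f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
    )


def get_scenario(
    name: str,
    b1: Optional[float] = None,
    n_steps: Optional[int] = None,
    s_max: Optional[float] = None,
) -> Scenario:
    """Look up a built-in scenario, optionally overriding b1/n_steps/s_max."""
    if name not in SCENARIO_NAMES:
        raise DomainError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        )
    if b1 is not None and name != "fig4":
        raise DomainError("the b1 sweep axis only applies to fig4")
    scenario = _build(name, float(b1) if b1 is not None else 4.0)
    params = scenario.params
    if n_steps is not None:
        params = replace(params, n_steps=int(n_steps))
    if s_max is not None:
        params = replace(params, s_max=float(s_max))
    if params is not scenario.params:
        scenario = replace(scenario, params=params)
    return scenario
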