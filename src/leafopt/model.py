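"""Core model types and pointwise evaluators.

The state is leaf area ``L(t)`` on a growing season ``[0, T]`` (t=0 leaf
flush, t=T shedding).  Leaf area is lost at rate ``u + h(t)/(1 + b(t) s(t))``
where ``s(t)`` is the per-area production rate of a volatile protective
compound, ``h(t)`` the hazard, ``b(t)`` the per-unit effectiveness of the
compound and ``u`` a background loss rate.  The plant maximizes the season
total of net assimilation ``(p(t) - s(t)) L(t)``.

Two parametric rate families are supported: constants and
exponentially-modulated cosines ``c * exp[a1 + sign * b1 * cos(2*pi*t/T)]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .exceptions import ConsistencyError, DomainError

__all__ = [
    "RateFunction",
    "RateSet",
    "SeasonParams",
    "Trajectory",
    "eval_rate",
    "leaf_rhs",
    "objective_integrand",
    "hamiltonian",
]

_FAMILIES = ("constant", "exp_cosine")
_T_EPS = 1e-9  # slack for floating-point endpoints of [0, T]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class RateFunction:
    """A positive rate defined on one season ``[0, period]``.

    family ``"constant"``: value is ``level`` everywhere.
    family ``"exp_cosine"``: value is
    ``scale * exp[a1 + sign * b1 * cos(2*pi*t/period)]``; with ``sign=-1``
    the maximum ``scale*exp[a1+b1]`` sits at mid-season ``t=period/2`` and
    the minimum ``scale*exp[a1-b1]`` at the season boundaries.
    """

    family: str
    level: float = 1.0
    a1: float = 0.0
    b1: float = 0.0
    scale: float = 1.0
    sign: int = -1
    period: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise DomainError(f"unknown rate family {self.family!r}")
        if not self.period > 0:
            raise DomainError("period must be positive")
        if self.family == "constant":
            if self.level < 0:
                raise DomainError("constant rate level must be non-negative")
        else:
            if self.sign not in (-1, 1):
                raise DomainError("sign_flag must be +1 or -1")
            if self.scale <= 0:
                raise DomainError("exp_cosine scale must be positive")
            if self.b1 < 0:
                raise DomainError("shape factor b1 must be non-negative")

    @classmethod
    def constant(cls, level: float, period: float = 1.0) -> "RateFunction":
        return cls(family="constant", level=float(level), period=float(period))

    @classmethod
    def exp_cosine(
        cls,
        a1: float,
        b1: float,
        scale: float = 1.0,
        sign: int = -1,
        period: float = 1.0,
    ) -> "RateFunction":
        return cls(
            family="exp_cosine",
            a1=float(a1),
            b1=float(b1),
            scale=float(scale),
            sign=int(sign),
            period=float(period),
        )

    @property
    def is_constant(self) -> bool:
        return self.family == "constant" or self.b1 == 0.0

    def with_period(self, period: float) -> "RateFunction":
        return replace(self, period=float(period))

    def __call__(self, t: ArrayLike) -> ArrayLike:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -_T_EPS) or np.any(t_arr > self.period + _T_EPS):
            raise DomainError(
                f"time outside the season [0, {self.period}]: {t!r}"
            )
        if self.family == "constant":
            out = np.full_like(t_arr, self.level, dtype=float)
        else:
            out = self.scale * np.exp(
                self.a1 + self.sign * self.b1 * np.cos(2.0 * np.pi * t_arr / self.period)
            )
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out


def eval_rate(rate: RateFunction, t: ArrayLike) -> ArrayLike:
    """Evaluate ``rate`` at time(s) ``t`` in ``[0, period]``."""
    return rate(t)


@dataclass(frozen=True)
class RateSet:
    """The three seasonal rates plus the background loss rate ``u``.

    ``b_eff`` is the per-unit effectiveness of the compound; it is named to
    avoid collision with the cosine shape factor ``b1`` of
    :class:`RateFunction`.
    """

    p: RateFunction
    h: RateFunction
    b_eff: RateFunction
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise DomainError("background loss rate u must be non-negative")
        periods = {self.p.period, self.h.period, self.b_eff.period}
        if max(periods) - min(periods) > _T_EPS:
            raise DomainError("p, h and b_eff must share the same season length")

    @property
    def period(self) -> float:
        return self.p.period

    @property
    def is_constant(self) -> bool:
        return self.p.is_constant and self.h.is_constant and self.b_eff.is_constant


@dataclass(frozen=True)
class SeasonParams:
    """Season length, initial state, control bound and grid resolution."""

    T: float = 1.0
    L0: float = 1.0
    s_max: float = 0.132
    n_steps: int = 20_000

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise DomainError("season length T must be positive")
        if not self.L0 > 0:
            raise DomainError("initial leaf area L0 must be positive")
        if self.s_max < 0:
            raise DomainError("s_max must be non-negative")
        if self.n_steps < 100:
            raise DomainError("n_steps must be at least 100")


@dataclass
class Trajectory:
    """A discretized solution of the seasonal control problem."""

    t: np.ndarray
    L: np.ndarray
    lam: np.ndarray
    s: np.ndarray
    p_vals: np.ndarray
    h_vals: np.ndarray
    b_vals: np.ndarray
    H_vals: np.ndarray
    phi: float
    s_max: float

    def validate(self) -> None:
        n = self.t.shape[0]
        arrays = (self.L, self.lam, self.s, self.p_vals, self.h_vals,
                  self.b_vals, self.H_vals)
        if any(a.shape != (n,) for a in arrays):
            raise ConsistencyError("trajectory arrays have mismatched lengths")
        if self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ConsistencyError("time grid must ascend from 0")
        tol = 1e-9 * max(self.s_max, 1.0)
        if np.any(self.s < -tol) or np.any(self.s > self.s_max + tol):
            raise ConsistencyError("control violates [0, s_max]")
        if np.any(self.L <= 0.0):
            raise ConsistencyError("leaf area must stay strictly positive")
        if np.any(np.diff(self.L) > 1e-12 * self.L[0]):
            raise ConsistencyError("leaf area must be non-increasing")
        if abs(self.lam[-1]) > 1e-12:
            raise ConsistencyError("terminal marginal value must be zero")

    @property
    def T(self) -> float:
        return float(self.t[-1])


def leaf_rhs(L: float, t: float, s: ArrayLike, rates: RateSet) -> ArrayLike:
    """dL/dt = -(u + h(t)/(1 + b(t) s)) * L."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise DomainError("production rate s must be non-negative")
    out = -(rates.u + rates.h(t) / (1.0 + rates.b_eff(t) * s_arr)) * L
    return float(out) if np.ndim(s) == 0 else out


def objective_integrand(L: float, t: float, s: ArrayLike, rates: RateSet) -> ArrayLike:
    """Instantaneous net assimilation ``(p(t) - s) * L``."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise DomainError("production rate s must be non-negative")
    out = (rates.p(t) - s_arr) * L
    return float(out) if np.ndim(s) == 0 else out


def hamiltonian(L: float, lam: float, t: float, s: ArrayLike, rates: RateSet) -> ArrayLike:
    """Current-value Hamiltonian ``(p - s) L - lam (u + h/(1+b s)) L``.

    Strictly concave in ``s`` for ``lam > 0`` (the marginal benefit of extra
    production saturates as the hazard is already suppressed).
    """
    return objective_integrand(L, t, s, rates) + lam * leaf_rhs(L, t, s, rates)
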