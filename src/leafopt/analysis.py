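"""Seasonal diagnostics: switching times, phase structure, peak timing,
integrated stress, elasticities, and the marginal-value identity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, cumulative_trapezoid, quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .exceptions import (
    ConsistencyError,
    DomainError,
    ElasticityUndefinedError,
    UndefinedPeakError,
)
from .model import RateFunction, RateSet, SeasonParams, Trajectory
from .solver import SolverSettings, solve

__all__ = [
    "PhaseReport",
    "ElasticityReport",
    "SwitchingResult",
    "switching_time_constant",
    "switching_time_general",
    "total_heat_stress",
    "classify_phases",
    "peak_shift",
    "production_peak_time",
    "elasticity",
    "marginal_value_decomposition",
]

log = logging.getLogger(__name__)

#: Sentinel ordering for the constant-rate phase sequence check.
_PHASE_ORDER = {"max": 0, "interior": 1, "zero": 2}


@dataclass(frozen=True)
class PhaseReport:
    """Phase structure of a solved schedule.

    ``segments`` is an ordered list of ``(label, t_start, t_end)`` with
    labels in {"max", "interior", "zero"}.  ``t_phase1_end`` is the end of an
    initial maximum-rate phase (absent otherwise); ``t_s`` is the onset of a
    terminal zero-production phase (absent if production runs to ``T`` or
    never starts... in which case ``has_production`` is False).
    """

    has_production: bool
    segments: Tuple[Tuple[str, float, float], ...]
    t_phase1_end: Optional[float] = None
    t_s: Optional[float] = None

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(seg[0] for seg in self.segments)


@dataclass(frozen=True)
class ElasticityReport:
    """Log-log sensitivity of initial production to one parameter."""

    parameter: str
    value: float
    rel_step: float
    value_half_step: float

    @property
    def step_consistent(self) -> bool:
        scale = max(abs(self.value), abs(self.value_half_step), 1e-12)
        return abs(self.value - self.value_half_step) <= 1e-2 * scale + 1e-6


@dataclass(frozen=True)
class SwitchingResult:
    """Root(s) of the switching condition for general seasonal rates."""

    t_s: Optional[float]
    roots: Tuple[float, ...] = ()

    @property
    def multiple_roots(self) -> bool:
        return len(self.roots) > 1


def switching_time_constant(
    p: float, h: float, b: float, u: float, T: float
) -> Optional[float]:
    """Closed-form onset of the terminal no-production phase.

    With all rates constant,

        t_s = T - (1/(u+h)) * ln(1 / (1 - (u+h)/(p*b*h))).

    Returns ``None`` when production is never profitable: either
    ``p*b*h <= u + h`` (benefit never covers cost) or the season is too short
    (raw ``t_s < 0``).
    """
    if T <= 0:
        raise DomainError("season length T must be positive")
    if min(p, h, b) < 0 or u < 0:
        raise DomainError("rates must be non-negative")
    denom = p * b * h
    if denom <= u + h:
        return None
    t_s = T - math.log(1.0 / (1.0 - (u + h) / denom)) / (u + h)
    if t_s < 0:
        return None
    return t_s


def _cumulative_hazard_spline(h: RateFunction, T: float, n: int = 4096):
    t = np.linspace(0.0, T, n + 1)
    hv = np.asarray(h(t), dtype=float)
    H = cumulative_simpson(hv, x=t, initial=0.0)
    return CubicSpline(t, H)


def switching_time_general(
    rates: RateSet,
    params: SeasonParams,
    n_scan: int = 400,
) -> SwitchingResult:
    """Solve the switching condition for time-dependent rates.

    The onset ``t_s`` of the terminal zero-production phase satisfies

        1 / (b(t_s) h(t_s)) =
            int_{t_s}^{T} p(t') exp[- int_{t_s}^{t'} (u + h(t'')) dt''] dt'

    (the right-hand side is the future net production per leaf area under
    zero production).  The residual LHS - RHS is scanned on a grid and each
    bracketed sign change is polished with Brent's method.  With no sign
    change production is never profitable and the sentinel ``t_s=None`` is
    returned.  Multiple roots are all reported; ``t_s`` is the largest.
    """
    T = params.T
    u = rates.u
    Hc = _cumulative_hazard_spline(rates.h, T)

    def rhs(ts: float) -> float:
        def integrand(tp: float) -> float:
            return float(rates.p(tp)) * math.exp(
                -(u * (tp - ts) + float(Hc(tp)) - float(Hc(ts)))
            )

        val, _ = quad(integrand, ts, T, epsabs=1e-13, epsrel=1e-11, limit=200)
        return val

    def resid(ts: float) -> float:
        return 1.0 / (float(rates.b_eff(ts)) * float(rates.h(ts))) - rhs(ts)

    eps = 1e-9 * T
    ts_grid = np.linspace(eps, T - eps, n_scan)
    res = np.array([resid(ts) for ts in ts_grid])
    roots: List[float] = []
    for i in range(n_scan - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            roots.append(float(ts_grid[i]))
        elif r0 * r1 < 0:
            roots.append(float(brentq(resid, ts_grid[i], ts_grid[i + 1],
                                      xtol=1e-12, rtol=1e-14)))
    if res[-1] == 0.0:
        roots.append(float(ts_grid[-1]))
    if not roots:
        return SwitchingResult(t_s=None, roots=())
    if len(roots) > 1:
        log.warning("switching condition has %d roots; reporting the largest",
                    len(roots))
    return SwitchingResult(t_s=max(roots), roots=tuple(roots))


def total_heat_stress(h: RateFunction, T: Optional[float] = None) -> float:
    """Season-integrated hazard ``int_0^T h(t) dt`` by adaptive quadrature."""
    T = h.period if T is None else T
    val, err = quad(lambda t: float(h(t)), 0.0, T,
                    epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(val)


def _point_labels(traj: Trajectory) -> np.ndarray:
    g = traj.lam * traj.b_vals * traj.h_vals
    z2 = (1.0 + traj.b_vals * traj.s_max) ** 2
    labels = np.full(traj.t.shape, "interior", dtype=object)
    labels[g <= 1.0 + 1e-12] = "zero"  # ties land on the zero side
    if traj.s_max > 0:
        labels[g >= z2 * (1.0 - 1e-12)] = "max"
    else:
        labels[:] = "zero"
    return labels


def classify_phases(
    traj: Trajectory,
    rates: Optional[RateSet] = None,
    control_tol: float = 1e-8,
) -> PhaseReport:
    """Label the solved schedule into max / interior / zero phases.

    Phase boundaries between adjacent grid nodes are refined by bisection of
    the relevant threshold crossing of ``lam(t) b(t) h(t)`` (against 1, or
    against ``(1 + b(t) s_max)^2``), using a cubic interpolant of the
    costate; ``rates`` (when given) supply exact rate values between nodes.
    For constant rates the sequence must be a subsequence of
    max -> interior -> zero, otherwise a :class:`ConsistencyError` signals a
    solver fault.
    """
    labels = _point_labels(traj)
    t = traj.t
    lam_spline = CubicSpline(t, traj.lam)

    def g_minus(thresh_kind: str):
        if rates is not None:
            b_of = rates.b_eff
            h_of = rates.h
        else:
            b_of = lambda x: np.interp(x, t, traj.b_vals)  # noqa: E731
            h_of = lambda x: np.interp(x, t, traj.h_vals)  # noqa: E731

        def f(x: float) -> float:
            b = float(b_of(x))
            h = float(h_of(x))
            g = float(lam_spline(x)) * b * h
            if thresh_kind == "zero":
                return g - 1.0
            return g - (1.0 + b * traj.s_max) ** 2

        return f

    segments: List[Tuple[str, float, float]] = []
    start = t[0]
    for i in range(1, t.shape[0]):
        if labels[i] != labels[i - 1]:
            kind = "zero" if "zero" in (labels[i], labels[i - 1]) else "max"
            f = g_minus(kind)
            lo, hi = float(t[i - 1]), float(t[i])
            try:
                if f(lo) * f(hi) < 0:
                    boundary = float(brentq(f, lo, hi, xtol=control_tol))
                else:
                    boundary = 0.5 * (lo + hi)
            except ValueError:
                boundary = 0.5 * (lo + hi)
            segments.append((str(labels[i - 1]), float(start), boundary))
            start = boundary
    segments.append((str(labels[-1]), float(start), float(t[-1])))
    # drop zero-length artifacts
    segments = [s for s in segments if s[2] - s[1] > 0 or len(segments) == 1]

    has_production = any(lab != "zero" for lab, _, _ in segments)
    t_phase1_end = segments[0][2] if segments[0][0] == "max" else None
    t_s = None
    if segments[-1][0] == "zero" and has_production:
        t_s = segments[-1][1]

    if rates is not None and rates.is_constant:
        order = [_PHASE_ORDER[lab] for lab, _, _ in segments]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ConsistencyError(
                f"non-monotone phase sequence {[s[0] for s in segments]} "
                "under constant rates"
            )

    return PhaseReport(
        has_production=has_production,
        segments=tuple(segments),
        t_phase1_end=t_phase1_end,
        t_s=t_s,
    )


def _quadratic_peak(t: np.ndarray, y: np.ndarray) -> float:
    """Grid argmax refined by a three-point parabola fit."""
    i = int(np.argmax(y))
    if i == 0 or i == y.shape[0] - 1:
        return float(t[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # flat or non-concave neighbourhood; keep the node
        return float(t[i])
    dt = t[i + 1] - t[i]
    return float(t[i] + 0.5 * dt * (y[i - 1] - y[i + 1]) / denom)


def production_peak_time(traj: Trajectory) -> float:
    """Time of maximum production, parabola-refined."""
    if np.max(traj.s) <= 0.0:
        raise UndefinedPeakError("no production anywhere in the season")
    return _quadratic_peak(traj.t, traj.s)


def peak_shift(traj: Trajectory) -> float:
    """Signed lag of the production peak behind the hazard peak.

    Positive values mean production peaks after the stress peak
    ("post-risk enhancement").  Requires a non-constant hazard and a
    non-trivial schedule.
    """
    if np.ptp(traj.h_vals) <= 1e-12 * max(1.0, float(np.max(traj.h_vals))):
        raise UndefinedPeakError("hazard is constant; its peak is undefined")
    t_s_peak = production_peak_time(traj)
    t_h_peak = _quadratic_peak(traj.t, traj.h_vals)
    return t_s_peak - t_h_peak


_SCALABLE = ("p", "h", "b", "u", "T", "L0")


def _scaled_problem(
    rates: RateSet, params: SeasonParams, name: str, factor: float
) -> Tuple[RateSet, SeasonParams]:
    if name == "p":
        rates = replace(rates, p=replace(rates.p, level=rates.p.level * factor))
    elif name == "h":
        rates = replace(rates, h=replace(rates.h, level=rates.h.level * factor))
    elif name == "b":
        rates = replace(
            rates, b_eff=replace(rates.b_eff, level=rates.b_eff.level * factor)
        )
    elif name == "u":
        rates = replace(rates, u=rates.u * factor)
    elif name == "T":
        T_new = params.T * factor
        rates = RateSet(
            p=rates.p.with_period(T_new),
            h=rates.h.with_period(T_new),
            b_eff=rates.b_eff.with_period(T_new),
            u=rates.u,
        )
        params = replace(params, T=T_new)
    elif name == "L0":
        params = replace(params, L0=params.L0 * factor)
    else:
        raise DomainError(f"unknown parameter {name!r}; choose from {_SCALABLE}")
    return rates, params


def _initial_production(
    rates: RateSet, params: SeasonParams, settings: SolverSettings
) -> float:
    traj = solve(rates, params, settings)
    return float(traj.s[0])


def elasticity(
    param_name: str,
    rates: RateSet,
    params: SeasonParams,
    settings: SolverSettings = SolverSettings(n_steps=4000),
    rel_step: float = 1e-3,
) -> ElasticityReport:
    """Elasticity ``d ln s(0) / d ln param`` by central log-differences.

    Requires constant rates (for ``p``, ``h``, ``b``) and a base point with
    ``0 < s(0) < s_max`` so the bound is not pinning the answer.  The report
    carries a half-step recomputation for a Richardson-style consistency
    check.
    """
    if param_name in ("p", "h", "b") and not rates.is_constant:
        raise DomainError(
            "elasticities of p/h/b are defined for constant-rate bases"
        )
    s0 = _initial_production(rates, params, settings)
    if s0 <= 0.0:
        raise ElasticityUndefinedError("s(0) = 0 at the base point")
    if s0 >= params.s_max * (1.0 - 1e-9):
        raise ElasticityUndefinedError(
            "s(0) sits on the s_max bound; increase s_max for a meaningful "
            "elasticity"
        )

    def central(step: float) -> float:
        up = _initial_production(
            *_scaled_problem(rates, params, param_name, math.exp(step)),
            settings,
        )
        dn = _initial_production(
            *_scaled_problem(rates, params, param_name, math.exp(-step)),
            settings,
        )
        if up <= 0.0 or dn <= 0.0:
            raise ElasticityUndefinedError(
                f"s(0) vanished while perturbing {param_name}"
            )
        return (math.log(up) - math.log(dn)) / (2.0 * step)

    value = central(rel_step)
    value_half = central(0.5 * rel_step)
    return ElasticityReport(
        parameter=param_name,
        value=value,
        rel_step=rel_step,
        value_half_step=value_half,
    )


def marginal_value_decomposition(
    traj: Trajectory,
    rates: RateSet,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Per-time diagnostic of what drives the schedule, plus a costate check.

    Columns: the immediate drivers of the control (``lam``, ``b``, ``h`` and
    their product ``lam_b_h`` whose position against 1 and
    ``(1+b*s_max)^2`` selects the control branch) and ``lam_identity``, the
    forward-computed future net production per unit leaf area

        lam(t) ?= int_t^T (p - s) exp[- int_t^{t'} (u + h/(1+b s))] dt'
               =  (1/L(t)) int_t^T (p - s) L dt'.

    A violation of this identity beyond ``tol`` (relative to max |lam|)
    raises :class:`ConsistencyError`.
    """
    t, L, lam, s = traj.t, traj.L, traj.lam, traj.s
    integrand = (traj.p_vals - s) * L
    cum = cumulative_trapezoid(integrand, t, initial=0.0)
    lam_identity = (cum[-1] - cum) / L
    scale = max(float(np.max(np.abs(lam))), 1e-12)
    err = np.abs(lam - lam_identity)
    if float(np.max(err)) > tol * scale:
        raise ConsistencyError(
            f"costate identity violated: max error {np.max(err):.3e} "
            f"(allowed {tol * scale:.3e})"
        )
    return pd.DataFrame({
        "t": t,
        "s": s,
        "lam": lam,
        "lam_identity": lam_identity,
        "identity_abs_err": err,
        "b": traj.b_vals,
        "h": traj.h_vals,
        "lam_b_h": lam * traj.b_vals * traj.h_vals,
        "saturation_threshold": (1.0 + traj.b_vals * traj.s_max) ** 2,
    })
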