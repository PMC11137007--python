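"""Pontryagin solver: costate backward pass, feedback control, forward pass.

The marginal value of leaf area ``lam(t)`` obeys

    dlam/dt = -(p(t) - s) + lam * (u + h(t) / (1 + b(t) s)),   lam(T) = 0,

with the control ``s`` substituted by the pointwise Hamiltonian maximizer at
every evaluation.  The maximizer is piecewise:

    s = 0                          if lam * b * h <= 1
    s = (sqrt(lam*b*h) - 1) / b    if 1 < lam * b * h < (1 + b*s_max)^2
    s = s_max                      if lam * b * h >= (1 + b*s_max)^2

The saturation threshold is the square ``(1 + b*s_max)^2``: it is the unique
value at which the interior stationary point reaches ``s_max``, which keeps
the law continuous in ``lam`` and equal to the argmax of the concave
Hamiltonian on ``[0, s_max]``.

Backward and forward passes default to a fixed-step classical Runge-Kutta
scheme with the feedback law evaluated at every internal stage; control
switches introduce derivative kinks that a fixed fine grid localizes well.
An adaptive path via :func:`scipy.integrate.solve_ivp` is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, SolverError
from .model import RateSet, SeasonParams, Trajectory

__all__ = [
    "SolverSettings",
    "optimal_control",
    "costate_rhs",
    "solve_backward",
    "solve_forward",
    "evaluate_objective",
    "solve",
]

# control-law signature used for feedback substitution:
# (lam, b, h, s_max) -> s.  Kept positional and scalar for speed inside the
# fixed-step loops; a corrupted law can be injected for mutation testing.
ControlLaw = Callable[[float, float, float, float], float]

ScheduleLike = Union[float, np.ndarray, Callable[[float], float]]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the backward/forward passes."""

    integrator: str = "fixed_rk4"
    n_steps: Optional[int] = None  # overrides SeasonParams.n_steps when set
    abs_tol: float = 1e-10
    rel_tol: float = 1e-8
    control_tol: float = 1e-8  # time tolerance for phase-boundary bisection

    def __post_init__(self) -> None:
        if self.integrator not in ("fixed_rk4", "adaptive"):
            raise DomainError(f"unknown integrator {self.integrator!r}")
        if self.n_steps is not None and self.n_steps < 100:
            raise DomainError("n_steps must be at least 100")
        if not (self.abs_tol > 0 and self.rel_tol > 0 and self.control_tol > 0):
            raise DomainError("tolerances must be positive")


def _oc_scalar(lam: float, b: float, h: float, s_max: float) -> float:
    """Scalar Hamiltonian-maximizing control."""
    bh = b * h
    if bh <= 0.0 or s_max <= 0.0:
        return 0.0
    g = lam * bh
    if g <= 1.0:
        return 0.0
    z = 1.0 + b * s_max
    if g >= z * z:
        return s_max
    return (math.sqrt(g) - 1.0) / b


def optimal_control(
    lam: Union[float, np.ndarray],
    t: Union[float, np.ndarray],
    rates: RateSet,
    s_max: float,
) -> Union[float, np.ndarray]:
    """Pointwise maximizer of the Hamiltonian over ``s in [0, s_max]``.

    Works on scalars or arrays (broadcast over ``lam`` and ``t``).
    """
    if s_max < 0:
        raise DomainError("s_max must be non-negative")
    lam_arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam_arr)):
        raise DomainError("lam must be finite")
    b = np.asarray(rates.b_eff(t), dtype=float)
    h = np.asarray(rates.h(t), dtype=float)
    bh = b * h
    g = lam_arr * bh
    z = 1.0 + b * s_max
    with np.errstate(invalid="ignore", divide="ignore"):
        interior = (np.sqrt(np.maximum(g, 1.0)) - 1.0) / np.where(b > 0, b, 1.0)
    s = np.where(g <= 1.0, 0.0, np.where(g >= z * z, s_max, interior))
    s = np.clip(s, 0.0, s_max)
    if np.ndim(lam) == 0 and np.ndim(t) == 0:
        return float(s)
    return s


def costate_rhs(lam: float, t: float, rates: RateSet, s_max: float) -> float:
    """Right-hand side of the costate equation with the feedback control."""
    b = rates.b_eff(t)
    h = rates.h(t)
    s = _oc_scalar(lam, b, h, s_max)
    return -(rates.p(t) - s) + lam * (rates.u + h / (1.0 + b * s))


def _grid(params: SeasonParams, settings: SolverSettings) -> np.ndarray:
    n = settings.n_steps if settings.n_steps is not None else params.n_steps
    return np.linspace(0.0, params.T, n + 1)


def _check_season(rates: RateSet, params: SeasonParams) -> None:
    if abs(rates.period - params.T) > 1e-9 * params.T:
        raise DomainError(
            f"rate period {rates.period} does not match season length {params.T}"
        )


def _precompute(rates: RateSet, t_grid: np.ndarray):
    """Rates at grid nodes and step midpoints (reused by all stage evals)."""
    t_mid = 0.5 * (t_grid[:-1] + t_grid[1:])
    return (
        rates.p(t_grid), rates.h(t_grid), rates.b_eff(t_grid),
        rates.p(t_mid), rates.h(t_mid), rates.b_eff(t_mid),
    )


def solve_backward(
    rates: RateSet,
    params: SeasonParams,
    settings: SolverSettings = SolverSettings(),
    control_law: Optional[ControlLaw] = None,
):
    """Integrate the costate equation from ``lam(T)=0`` back to ``t=0``.

    Returns ``(t_grid, lam, s)`` with the feedback control evaluated at every
    internal integrator stage and sampled on the grid nodes.
    """
    _check_season(rates, params)
    law = control_law if control_law is not None else _oc_scalar
    t_grid = _grid(params, settings)
    s_max = params.s_max
    u = rates.u

    if settings.integrator == "adaptive":
        def rhs(t, y):
            b = rates.b_eff(t)
            h = rates.h(t)
            s = law(y[0], b, h, s_max)
            return [-(rates.p(t) - s) + y[0] * (u + h / (1.0 + b * s))]

        sol = solve_ivp(
            rhs, (params.T, 0.0), [0.0], t_eval=t_grid[::-1],
            rtol=settings.rel_tol, atol=settings.abs_tol, method="RK45",
        )
        if not sol.success:
            raise SolverError(f"backward integration failed: {sol.message}")
        lam = sol.y[0][::-1].copy()
    else:
        n = t_grid.shape[0] - 1
        dt = params.T / n
        p_n, h_n, b_n, p_m, h_m, b_m = _precompute(rates, t_grid)
        lam = np.empty(n + 1)
        lam[n] = 0.0
        y = 0.0
        for i in range(n - 1, -1, -1):
            # step from t[i+1] down to t[i]
            pn1, hn1, bn1 = p_n[i + 1], h_n[i + 1], b_n[i + 1]
            pm, hm, bm = p_m[i], h_m[i], b_m[i]
            pn0, hn0, bn0 = p_n[i], h_n[i], b_n[i]

            s1 = law(y, bn1, hn1, s_max)
            k1 = -(pn1 - s1) + y * (u + hn1 / (1.0 + bn1 * s1))
            y2 = y - 0.5 * dt * k1
            s2 = law(y2, bm, hm, s_max)
            k2 = -(pm - s2) + y2 * (u + hm / (1.0 + bm * s2))
            y3 = y - 0.5 * dt * k2
            s3 = law(y3, bm, hm, s_max)
            k3 = -(pm - s3) + y3 * (u + hm / (1.0 + bm * s3))
            y4 = y - dt * k3
            s4 = law(y4, bn0, hn0, s_max)
            k4 = -(pn0 - s4) + y4 * (u + hn0 / (1.0 + bn0 * s4))

            y = y - dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not math.isfinite(y):
                raise SolverError(
                    f"non-finite costate at t={t_grid[i]:.6g} "
                    f"(step {i} of {n}); check rates and tolerances"
                )
            lam[i] = y

    b_nodes = np.asarray(rates.b_eff(t_grid), dtype=float)
    h_nodes = np.asarray(rates.h(t_grid), dtype=float)
    s = np.array([
        law(lam[i], b_nodes[i], h_nodes[i], s_max) for i in range(lam.shape[0])
    ])
    s = np.clip(s, 0.0, s_max)
    return t_grid, lam, s


def _schedule_on_grid(
    s_schedule: ScheduleLike, t_grid: np.ndarray, s_max: float
):
    """Node and midpoint control values for a schedule given as scalar,
    node array, or callable."""
    t_mid = 0.5 * (t_grid[:-1] + t_grid[1:])
    if callable(s_schedule):
        s_nodes = np.array([float(s_schedule(t)) for t in t_grid])
        s_mids = np.array([float(s_schedule(t)) for t in t_mid])
    else:
        s_arr = np.asarray(s_schedule, dtype=float)
        if s_arr.ndim == 0:
            s_nodes = np.full(t_grid.shape, float(s_arr))
            s_mids = np.full(t_mid.shape, float(s_arr))
        else:
            if s_arr.shape != t_grid.shape:
                raise DomainError(
                    f"schedule length {s_arr.shape[0]} does not match grid "
                    f"length {t_grid.shape[0]}"
                )
            s_nodes = s_arr
            s_mids = 0.5 * (s_arr[:-1] + s_arr[1:])
    tol = 1e-9 * max(s_max, 1.0)
    if np.any(s_nodes < -tol) or np.any(s_nodes > s_max + tol):
        raise DomainError("schedule violates the bounds [0, s_max]")
    return np.clip(s_nodes, 0.0, s_max), np.clip(s_mids, 0.0, s_max)


def _forward_rk4(
    t_grid: np.ndarray,
    s_nodes: np.ndarray,
    s_mids: np.ndarray,
    rates: RateSet,
    L0: float,
) -> np.ndarray:
    n = t_grid.shape[0] - 1
    dt = (t_grid[-1] - t_grid[0]) / n
    _, h_n, b_n, _, h_m, b_m = _precompute(rates, t_grid)
    u = rates.u
    L = np.empty(n + 1)
    L[0] = L0
    y = L0
    for i in range(n):
        r0 = u + h_n[i] / (1.0 + b_n[i] * s_nodes[i])
        rm = u + h_m[i] / (1.0 + b_m[i] * s_mids[i])
        r1 = u + h_n[i + 1] / (1.0 + b_n[i + 1] * s_nodes[i + 1])
        k1 = -r0 * y
        k2 = -rm * (y + 0.5 * dt * k1)
        k3 = -rm * (y + 0.5 * dt * k2)
        k4 = -r1 * (y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        L[i + 1] = y
    return L


def solve_forward(
    s_schedule: ScheduleLike,
    rates: RateSet,
    params: SeasonParams,
    settings: SolverSettings = SolverSettings(),
) -> np.ndarray:
    """Integrate the leaf-area equation forward from ``L(0) = L0``.

    ``s_schedule`` may be a scalar, an array on the grid nodes, or a callable
    of time; values must respect ``[0, s_max]``.
    """
    _check_season(rates, params)
    t_grid = _grid(params, settings)

    if settings.integrator == "adaptive":
        if callable(s_schedule):
            s_of_t = s_schedule
        else:
            s_arr = np.asarray(s_schedule, dtype=float)
            if s_arr.ndim == 0:
                s_of_t = lambda t: float(s_arr)  # noqa: E731
            else:
                if s_arr.shape != t_grid.shape:
                    raise DomainError("schedule length does not match grid")
                s_of_t = lambda t: float(np.interp(t, t_grid, s_arr))  # noqa: E731
        tol = 1e-9 * max(params.s_max, 1.0)
        probe = np.array([s_of_t(t) for t in t_grid])
        if np.any(probe < -tol) or np.any(probe > params.s_max + tol):
            raise DomainError("schedule violates the bounds [0, s_max]")

        def rhs(t, y):
            s = min(max(s_of_t(t), 0.0), params.s_max)
            return [-(rates.u + rates.h(t) / (1.0 + rates.b_eff(t) * s)) * y[0]]

        sol = solve_ivp(
            rhs, (0.0, params.T), [params.L0], t_eval=t_grid,
            rtol=settings.rel_tol, atol=settings.abs_tol, method="RK45",
        )
        if not sol.success:
            raise SolverError(f"forward integration failed: {sol.message}")
        return sol.y[0].copy()

    s_nodes, s_mids = _schedule_on_grid(s_schedule, t_grid, params.s_max)
    return _forward_rk4(t_grid, s_nodes, s_mids, rates, params.L0)


def evaluate_objective(
    t_grid: np.ndarray,
    L: np.ndarray,
    s: np.ndarray,
    rates: RateSet,
) -> float:
    """Season total of net assimilation, trapezoid rule on the grid."""
    p_vals = np.asarray(rates.p(t_grid), dtype=float)
    return float(np.trapezoid((p_vals - s) * L, t_grid))


def solve(
    rates: RateSet,
    params: SeasonParams,
    settings: SolverSettings = SolverSettings(),
    control_law: Optional[ControlLaw] = None,
) -> Trajectory:
    """Full solve: backward costate pass, forward state pass, objective.

    The forward pass re-derives stage controls from the (linearly
    interpolated) costate so that control kinks land where the law, not the
    interpolant of ``s``, puts them.
    """
    _check_season(rates, params)
    law = control_law if control_law is not None else _oc_scalar
    t_grid, lam, s = solve_backward(rates, params, settings, control_law)

    if settings.integrator == "adaptive":
        def s_of_t(t: float) -> float:
            lam_t = float(np.interp(t, t_grid, lam))
            return law(lam_t, rates.b_eff(t), rates.h(t), params.s_max)

        L = solve_forward(s_of_t, rates, params, settings)
    else:
        t_mid = 0.5 * (t_grid[:-1] + t_grid[1:])
        lam_mid = 0.5 * (lam[:-1] + lam[1:])
        b_m = np.asarray(rates.b_eff(t_mid), dtype=float)
        h_m = np.asarray(rates.h(t_mid), dtype=float)
        s_mids = np.array([
            law(lam_mid[i], b_m[i], h_m[i], params.s_max)
            for i in range(lam_mid.shape[0])
        ])
        s_mids = np.clip(s_mids, 0.0, params.s_max)
        L = _forward_rk4(t_grid, np.clip(s, 0.0, params.s_max), s_mids,
                         rates, params.L0)

    phi = evaluate_objective(t_grid, L, s, rates)
    p_vals = np.asarray(rates.p(t_grid), dtype=float)
    h_vals = np.asarray(rates.h(t_grid), dtype=float)
    b_vals = np.asarray(rates.b_eff(t_grid), dtype=float)
    H_vals = (p_vals - s) * L - lam * (rates.u + h_vals / (1.0 + b_vals * s)) * L

    traj = Trajectory(
        t=t_grid, L=L, lam=lam, s=s,
        p_vals=p_vals, h_vals=h_vals, b_vals=b_vals, H_vals=H_vals,
        phi=phi, s_max=params.s_max,
    )
    traj.validate()
    return traj
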