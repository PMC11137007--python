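"""Independent brute-force validation of the Pontryagin solution.

Two instruments:

* :func:`direct_optimize` — direct search over piecewise-constant schedules
  (``n_bins`` equal time bins, ``n_levels`` equally spaced control levels),
  exhaustive for small spaces and coordinate-ascent otherwise.
* :func:`dominance_test` — the solved schedule must (weakly) beat seeded
  random feasible schedules and local perturbations of itself.

Every candidate is scored with the same fixed-step forward integrator and
trapezoid quadrature as the main solver, so any discrepancy isolates the
control law rather than the integrator.  For the exhaustive search this is
done by factoring the season at the bin boundaries: the state equation is
linear in ``L``, so one forward pass per (bin, level) pair yields a survival
factor ``F`` and a per-unit-leaf-area yield ``G``, and the objective of any
candidate composes exactly as a full-season pass whose grid is aligned with
the bin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .exceptions import DomainError
from .model import RateSet, SeasonParams
from .solver import (
    SolverSettings,
    _forward_rk4,
    _precompute,
    evaluate_objective,
    solve_forward,
)

__all__ = [
    "OracleResult",
    "DominanceReport",
    "direct_optimize",
    "dominance_test",
    "swapped_threshold_control",
]

_EXHAUSTIVE_CAP = 200_000_000  # candidate count above which ascent is forced


@dataclass(frozen=True)
class OracleResult:
    n_bins: int
    n_levels: int
    schedule: Tuple[float, ...]  # one level per bin
    phi: float
    n_evaluated: int
    mode: str  # "exhaustive" or "ascent"


@dataclass(frozen=True)
class DominanceReport:
    passed: bool
    phi_solution: float
    phi_best_candidate: float
    margin: float  # phi_solution - phi_best_candidate
    n_candidates: int
    seed: int
    worst_schedule: Optional[np.ndarray] = None


def _bin_grid(params: SeasonParams, n_bins: int) -> Tuple[np.ndarray, int]:
    """Full-season grid whose nodes include every bin boundary."""
    per_bin = max(50, -(-params.n_steps // n_bins))  # ceil division
    t_grid = np.linspace(0.0, params.T, n_bins * per_bin + 1)
    return t_grid, per_bin


def _bin_factors(
    rates: RateSet, n_bins: int, levels: np.ndarray,
    per_bin: int, t_grid: np.ndarray,
):
    """Survival factor F[k, l] and per-area yield G[k, l] for each bin/level.

    Computed with the solver's own RK4 step and trapezoid rule on the
    sub-grid of bin ``k``, starting from unit leaf area.
    """
    n_levels = levels.shape[0]
    F = np.empty((n_bins, n_levels))
    G = np.empty((n_bins, n_levels))
    for k in range(n_bins):
        lo = k * per_bin
        sub_t = t_grid[lo:lo + per_bin + 1]
        for j, lev in enumerate(levels):
            s_nodes = np.full(sub_t.shape, lev)
            s_mids = np.full(sub_t.shape[0] - 1, lev)
            L = _forward_rk4(sub_t, s_nodes, s_mids, rates, 1.0)
            F[k, j] = L[-1]
            p_vals = np.asarray(rates.p(sub_t), dtype=float)
            G[k, j] = float(np.trapezoid((p_vals - lev) * L, sub_t))
    return F, G


def _schedule_nodes(
    levels_per_bin: np.ndarray, t_grid: np.ndarray, per_bin: int
) -> np.ndarray:
    """Node samples of a piecewise-constant schedule (right bin at edges)."""
    n_bins = levels_per_bin.shape[0]
    idx = np.minimum(np.arange(t_grid.shape[0]) // per_bin, n_bins - 1)
    return levels_per_bin[idx]


def _compose_phi(schedule: np.ndarray, F: np.ndarray, G: np.ndarray) -> float:
    phi = 0.0
    surv = 1.0
    for k, j in enumerate(schedule):
        phi += surv * G[k, j]
        surv *= F[k, j]
    return phi


def direct_optimize(
    rates: RateSet,
    params: SeasonParams,
    n_bins: int = 8,
    n_levels: int = 9,
    mode: Optional[str] = None,
    max_sweeps: int = 200,
) -> OracleResult:
    """Best piecewise-constant schedule by direct search.

    ``mode`` defaults to exhaustive when ``n_levels ** n_bins`` is tractable
    (and ``n_bins <= 12``), otherwise coordinate ascent.  The returned
    ``phi`` is re-scored by a single full-season forward pass of the best
    schedule, which matches the composed value to round-off.
    """
    if n_bins < 1 or n_levels < 2:
        raise DomainError("need n_bins >= 1 and n_levels >= 2")
    levels = np.linspace(0.0, params.s_max, n_levels)
    t_grid, per_bin = _bin_grid(params, n_bins)
    F, G = _bin_factors(rates, n_bins, levels, per_bin, t_grid)

    n_space = n_levels ** n_bins
    if mode is None:
        mode = "exhaustive" if (n_bins <= 12 and n_space <= _EXHAUSTIVE_CAP) \
            else "ascent"

    if mode == "exhaustive":
        if n_space > _EXHAUSTIVE_CAP:
            raise DomainError(
                f"{n_space} candidates exceed the exhaustive cap; use ascent"
            )
        # Backward accumulation over the full candidate space.  V holds the
        # objective of every suffix (bins k..n_bins-1); prepending bin k is
        # an outer product because L enters the dynamics linearly.
        V = G[n_bins - 1].copy()
        for k in range(n_bins - 2, -1, -1):
            V = (G[k][:, None] + F[k][:, None] * V[None, :]).ravel()
        best_flat = int(np.argmax(V))
        idx = np.array(np.unravel_index(best_flat, (n_levels,) * n_bins))
        n_evaluated = n_space
    else:
        idx = np.full(n_bins, n_levels // 2, dtype=int)
        best = _compose_phi(idx, F, G)
        n_evaluated = 1
        for _ in range(max_sweeps):
            improved = False
            for k in range(n_bins):
                cur = idx[k]
                for j in range(n_levels):
                    if j == cur:
                        continue
                    idx[k] = j
                    val = _compose_phi(idx, F, G)
                    n_evaluated += 1
                    if val > best + 1e-15:
                        best = val
                        cur = j
                        improved = True
                idx[k] = cur
            if not improved:
                break

    best_levels = levels[idx]
    s_nodes = _schedule_nodes(best_levels, t_grid, per_bin)
    settings = SolverSettings(n_steps=t_grid.shape[0] - 1)
    L = solve_forward(s_nodes, rates, params, settings)
    phi = evaluate_objective(t_grid, L, s_nodes, rates)
    return OracleResult(
        n_bins=n_bins,
        n_levels=n_levels,
        schedule=tuple(float(x) for x in best_levels),
        phi=phi,
        n_evaluated=n_evaluated,
        mode=mode,
    )


def _forward_batch_phi(
    S: np.ndarray, t_grid: np.ndarray, rates: RateSet, L0: float
) -> np.ndarray:
    """Objective of many node-sampled schedules at once (vectorized RK4 +
    trapezoid, identical stepping to the scalar integrator)."""
    n = t_grid.shape[0] - 1
    dt = (t_grid[-1] - t_grid[0]) / n
    p_n, h_n, b_n, _, h_m, b_m = _precompute(rates, t_grid)
    u = rates.u
    L = np.full(S.shape[0], L0)
    phi = np.zeros(S.shape[0])
    for i in range(n):
        s0 = S[:, i]
        s1 = S[:, i + 1]
        sm = 0.5 * (s0 + s1)
        r0 = u + h_n[i] / (1.0 + b_n[i] * s0)
        rm = u + h_m[i] / (1.0 + b_m[i] * sm)
        r1 = u + h_n[i + 1] / (1.0 + b_n[i + 1] * s1)
        k1 = -r0 * L
        k2 = -rm * (L + 0.5 * dt * k1)
        k3 = -rm * (L + 0.5 * dt * k2)
        k4 = -r1 * (L + dt * k3)
        L_next = L + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        phi += 0.5 * dt * ((p_n[i] - s0) * L + (p_n[i + 1] - s1) * L_next)
        L = L_next
    return phi


def dominance_test(
    traj,
    rates: RateSet,
    params: SeasonParams,
    n_random: int = 500,
    seed: int = 1,
    n_perturb: int = 100,
    random_bins: int = 20,
    eps_frac: float = 0.05,
    tol: float = 1e-8,
) -> DominanceReport:
    """Check that the solved schedule is not beaten by any probe schedule.

    Probes are ``n_random`` piecewise-constant schedules with i.i.d. uniform
    levels on ``[0, s_max]`` plus ``n_perturb`` local bumps of the solution
    itself (±``eps_frac * s_max`` on windows of width ``eps_frac * T``).
    All probes are scored on the trajectory's own grid.
    """
    if n_random < 100:
        raise DomainError("n_random must be at least 100")
    rng = np.random.default_rng(seed)
    t_grid = traj.t
    n_nodes = t_grid.shape[0]
    s_max = params.s_max

    schedules = []
    if s_max > 0:
        levels = rng.uniform(0.0, s_max, size=(n_random, random_bins))
        bin_idx = np.minimum(
            (t_grid / params.T * random_bins).astype(int), random_bins - 1
        )
        schedules.append(levels[:, bin_idx])
    else:
        schedules.append(np.zeros((n_random, n_nodes)))

    eps = eps_frac * s_max
    width = eps_frac * params.T
    perturbed = np.repeat(traj.s[None, :], n_perturb, axis=0)
    for r in range(n_perturb):
        t0 = rng.uniform(0.0, params.T - width)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        window = (t_grid >= t0) & (t_grid <= t0 + width)
        perturbed[r, window] = np.clip(
            perturbed[r, window] + sign * eps, 0.0, s_max
        )
    schedules.append(perturbed)

    S = np.vstack(schedules)
    phi = _forward_batch_phi(S, t_grid, rates, params.L0)
    best = int(np.argmax(phi))
    margin = float(traj.phi - phi[best])
    passed = margin >= -tol
    return DominanceReport(
        passed=passed,
        phi_solution=float(traj.phi),
        phi_best_candidate=float(phi[best]),
        margin=margin,
        n_candidates=S.shape[0],
        seed=seed,
        worst_schedule=None if passed else S[best].copy(),
    )


def swapped_threshold_control(lam: float, b: float, h: float, s_max: float) -> float:
    """Deliberately wrong control law (branch thresholds swapped).

    Produces at the maximum rate exactly where production is worthless and
    vice versa.  Used as a mutation probe: a sound dominance suite must
    reject schedules generated with this law.
    """
    bh = b * h
    if bh <= 0.0 or s_max <= 0.0:
        return 0.0
    g = lam * bh
    z = 1.0 + b * s_max
    if g <= 1.0:
        return s_max
    if g >= z * z:
        return 0.0
    return (np.sqrt(g) - 1.0) / b
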