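"""Bound-constrained global optimiser: particle swarm + pattern search.

A global-best particle swarm (inertia 0.72, cognitive/social weights 1.49)
explores the box; positions leaving a bound are reflected back inside to
preserve swarm diversity.  The swarm's best point is then polished by a
coordinate pattern search (poll steps along each axis, halving the step on
failure) until the step shrinks below tolerance or the evaluation budget is
exhausted.  Fully deterministic for a given seed.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = ["SwarmConfig", "SwarmResult", "minimize_pswarm"]


@dataclasses.dataclass(frozen=True)
class SwarmConfig:
    n_particles: int = 40
    iterations: int = 300
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    tol: float = 1e-8            # pattern-search step tolerance (relative)
    patience: int = 40           # swarm iterations without improvement before
                                 # moving on to the polish phase
    polish_budget: int = 2000    # max evaluations in the pattern search
    seed: int = 0


@dataclasses.dataclass
class SwarmResult:
    x: np.ndarray
    cost: float
    cost_trace: np.ndarray       # best-so-far cost per swarm iteration
    n_evaluations: int
    seed: int
    converged: bool
    message: str


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect coordinates back into [lo, hi] (repeatedly, for big steps)."""
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def minimize_pswarm(
    fun: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: SwarmConfig | None = None,
) -> SwarmResult:
    """Minimise ``fun`` over a box.

    ``fun`` must return a finite scalar for any in-bounds point (use a
    large penalty value for failed evaluations, not an exception).
    """
    cfg = SwarmConfig() if config is None else config
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(~np.isfinite(lo) | ~np.isfinite(hi)) or np.any(lo > hi):
        raise ValueError("bounds must be finite with lower <= upper")
    if cfg.iterations < 1:
        raise ValueError("iteration budget must be >= 1")
    dim = lo.size
    span = hi - lo
    rng = np.random.default_rng(cfg.seed)
    n_eval = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return float(fun(x))

    # ----- global phase: particle swarm ---------------------------------
    pos = lo + span * rng.random((cfg.n_particles, dim))
    vel = 0.1 * span * (2.0 * rng.random((cfg.n_particles, dim)) - 1.0)
    pcost = np.array([f(x) for x in pos])
    pbest = pos.copy()
    pbest_cost = pcost.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    trace = [gbest_cost]
    stall = 0
    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.n_particles, dim))
        r2 = rng.random((cfg.n_particles, dim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        pos = _reflect(pos + vel, lo, hi)
        improved_any = False
        for i in range(cfg.n_particles):
            c = f(pos[i])
            if c < pbest_cost[i]:
                pbest_cost[i] = c
                pbest[i] = pos[i]
                if c < gbest_cost:
                    gbest_cost = c
                    gbest = pos[i].copy()
                    improved_any = True
        trace.append(gbest_cost)
        stall = 0 if improved_any else stall + 1
        if gbest_cost <= cfg.tol**2 or stall >= cfg.patience:
            break

    # ----- local phase: coordinate pattern search -----------------------
    step = 0.05 * span.copy()
    min_step = cfg.tol * np.maximum(span, 1.0)
    budget = cfg.polish_budget
    x, c0 = gbest.copy(), gbest_cost
    while budget > 0 and np.any(step > min_step):
        moved = False
        for d in range(dim):
            for sgn in (+1.0, -1.0):
                if budget <= 0:
                    break
                trial = x.copy()
                trial[d] = np.clip(trial[d] + sgn * step[d], lo[d], hi[d])
                if trial[d] == x[d]:
                    continue
                c = f(trial)
                budget -= 1
                if c < c0:
                    x, c0 = trial, c
                    moved = True
                    break
        if not moved:
            step *= 0.5
    gbest, gbest_cost = x, c0
    trace.append(gbest_cost)

    converged = bool(np.all(step <= min_step) or gbest_cost <= cfg.tol**2)
    return SwarmResult(
        x=gbest,
        cost=gbest_cost,
        cost_trace=np.minimum.accumulate(np.array(trace)),
        n_evaluations=n_eval,
        seed=cfg.seed,
        converged=converged,
        message="pattern-search step below tolerance"
        if converged
        else "evaluation budget exhausted",
    )
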