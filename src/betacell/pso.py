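"""Particle swarm optimization (global box-constrained minimizer).

Standard constricted PSO: inertia 0.72, cognitive/social accelerations
1.49, positions clipped to the box, velocities capped at the box width.
Objective failures (exceptions or non-finite values) are penalized with
a large finite value so a bad particle does not kill a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

PENALTY = 1e12


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    trace: np.ndarray  # best-so-far objective per iteration
    n_failures: int


def pso_minimize(func: Callable[[np.ndarray], float], lb: np.ndarray, ub: np.ndarray,
                 n_particles: int = 50, iterations: int = 2000,
                 inertia: float = 0.72, cognitive: float = 1.49, social: float = 1.49,
                 seed: int | np.random.Generator = 0,
                 init: np.ndarray | None = None) -> PSOResult:
    """Minimize ``func`` over the box [lb, ub].

    ``init`` optionally seeds one particle (e.g. the nominal parameter
    estimate).  The best-so-far trace is monotone non-increasing by
    construction.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if lb.shape != ub.shape or np.any(lb >= ub):
        raise ValueError("bounds must satisfy lb < ub elementwise")
    d = lb.size
    rng = np.random.default_rng(seed)

    pos = rng.uniform(lb, ub, size=(n_particles, d))
    if init is not None:
        pos[0] = np.clip(init, lb, ub)
    span = ub - lb
    vel = rng.uniform(-span, span, size=(n_particles, d)) * 0.1

    n_failures = 0

    def safe(x: np.ndarray) -> float:
        nonlocal n_failures
        try:
            v = float(func(x))
        except Exception:
            n_failures += 1
            return PENALTY
        if not np.isfinite(v):
            n_failures += 1
            return PENALTY
        return v

    pbest = pos.copy()
    pbest_f = np.array([safe(p) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    if not np.isfinite(gbest_f) or gbest_f >= PENALTY:
        if np.all(pbest_f >= PENALTY):
            raise RuntimeError("all initial particles failed to evaluate")

    trace = np.empty(iterations)
    for it in range(iterations):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        vel = (inertia * vel
               + cognitive * r1 * (pbest - pos)
               + social * r2 * (gbest - pos))
        np.clip(vel, -span, span, out=vel)
        pos = np.clip(pos + vel, lb, ub)
        for k in range(n_particles):
            f = safe(pos[k])
            if f < pbest_f[k]:
                pbest_f[k] = f
                pbest[k] = pos[k]
                if f < gbest_f:
                    gbest_f = f
                    gbest = pos[k].copy()
        trace[it] = gbest_f
    return PSOResult(best_x=gbest, best_f=gbest_f, trace=trace, n_failures=n_failures)
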