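"""Global-best particle swarm optimization.

Plain PSO with inertia and cognitive/social acceleration, box bounds enforced
by clamp-and-zero-velocity, and a stall-based stop rule: the run ends once
the global best has not improved (relatively) for a configured number of
consecutive iterations, or at a hard iteration cap.  Fully deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class PSOConfig:
    swarm_size: int = 100
    stall_iterations: int = 20
    max_iterations: int = 1000
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    stall_rel_tol: float = 1e-6     # improvement below this is a stall iteration
    seed: int = 0


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    n_iterations: int
    history: list = field(default_factory=list)   # global best per iteration
    n_evals: int = 0


def run_pso(objective: Callable[[np.ndarray], float],
            lower: np.ndarray, upper: np.ndarray,
            config: PSOConfig | None = None,
            rng: np.random.Generator | None = None) -> PSOResult:
    """Minimize ``objective`` over the box [lower, upper]."""
    cfg = config or PSOConfig()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(~np.isfinite(lower)) or np.any(~np.isfinite(upper)):
        raise ValueError("bounds must be finite arrays of equal shape")
    if np.any(upper <= lower):
        raise ValueError("upper bounds must exceed lower bounds")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dim = lower.size
    span = upper - lower
    vmax = 0.5 * span

    x = lower + rng.uniform(size=(cfg.swarm_size, dim)) * span
    v = rng.uniform(-0.1, 0.1, size=(cfg.swarm_size, dim)) * span
    f = np.array([objective(xi) for xi in x])
    n_evals = cfg.swarm_size
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])

    history = [gbest_f]
    stall = 0
    it = 0
    while it < cfg.max_iterations and stall < cfg.stall_iterations:
        it += 1
        r1 = rng.uniform(size=(cfg.swarm_size, dim))
        r2 = rng.uniform(size=(cfg.swarm_size, dim))
        v = (cfg.inertia * v
             + cfg.c1 * r1 * (pbest_x - x)
             + cfg.c2 * r2 * (gbest_x[None, :] - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        out_lo, out_hi = x < lower, x > upper
        v[out_lo | out_hi] = 0.0                    # clamp-and-log policy
        np.clip(x, lower, upper, out=x)

        f = np.array([objective(xi) for xi in x])
        n_evals += cfg.swarm_size
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        new_best = float(pbest_f[g])
        rel_gain = (gbest_f - new_best) / max(abs(gbest_f), 1e-30)
        if new_best < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), new_best
        stall = 0 if rel_gain > cfg.stall_rel_tol else stall + 1
        history.append(gbest_f)

    return PSOResult(best_x=gbest_x, best_f=gbest_f, n_iterations=it,
                     history=history, n_evals=n_evals)
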