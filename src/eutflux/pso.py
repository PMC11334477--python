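"""Particle swarm optimization (constriction-factor variant).

Global-best PSO with Clerc-Kennedy constriction (chi = 0.729, c1 = c2 =
1.49445) and reflecting bounds.  Deterministic under a fixed seed.  This is
the global optimizer used to fit the dynamic isotopic model, whose weighted
sum-of-squares landscape is multimodal in the flux parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

CHI = 0.729
C1 = 1.49445
C2 = 1.49445


@dataclass
class PsoResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray  # best objective after each iteration (non-increasing)
    n_evaluations: int
    settings: dict = field(default_factory=dict)


def minimize_pso(
    func: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    *,
    iterations: int = 2000,
    swarm_size: int = 50,
    seed: int = 0,
    infeasible_value: float = 1e30,
) -> PsoResult:
    """Minimize ``func`` over a box by global-best particle swarm.

    Particles start uniformly in the box with zero velocity; velocities
    follow the constriction update and positions reflect off the bounds.
    Raises if every initial particle evaluates to ``infeasible_value`` or
    worse (a sign the bounds exclude all feasible parameter sets).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("PSO requires finite bounds for every parameter")
    if np.any(hi <= lo):
        raise ValueError("upper bounds must exceed lower bounds")
    dim = lo.size
    rng = np.random.default_rng(seed)

    x = lo + (hi - lo) * rng.random((swarm_size, dim))
    v = np.zeros_like(x)
    f = np.array([float(func(xi)) for xi in x])
    n_eval = swarm_size
    if np.all(f >= infeasible_value):
        raise RuntimeError(
            "all initial particles are infeasible; widen the bounds"
        )

    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])
    trace = np.empty(iterations)

    span = hi - lo
    for it in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        v = CHI * (v + C1 * r1 * (pbest_x - x) + C2 * r2 * (gbest_x - x))
        x = x + v
        # reflect off the box, flipping the offending velocity component
        for _ in range(2):  # at most two reflections for any sane step
            under = x < lo
            over = x > hi
            if not (under.any() or over.any()):
                break
            x = np.where(under, 2 * lo - x, x)
            x = np.where(over, 2 * hi - x, x)
            v = np.where(under | over, -v, v)
        np.clip(x, lo, hi, out=x)
        np.clip(v, -span, span, out=v)

        f = np.array([float(func(xi)) for xi in x])
        n_eval += swarm_size
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace[it] = gbest_f

    return PsoResult(
        x=gbest_x,
        fun=gbest_f,
        trace=trace,
        n_evaluations=n_eval,
        settings={
            "iterations": iterations,
            "swarm_size": swarm_size,
            "seed": seed,
            "chi": CHI,
            "c1": C1,
            "c2": C2,
        },
    )
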