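"""Hybrid GA-QPSO continuous optimizer.

Quantum-behaved particle swarm: each particle is drawn around a
per-particle attractor (a random convex combination of its personal best
and the global best) at a distance scaled by the contraction-expansion
coefficient beta and the spread of the swarm's mean-best position.  Beta
decreases linearly over iterations, shifting from exploration to
exploitation.  A genetic layer applies arithmetic crossover and uniform
resampling mutation to the position vectors, with per-individual
probabilities adapted by fitness rank (better individuals mutate less).

The engine maximizes an arbitrary objective over a box; it is shared by
the binary sensor-subset selector (positions thresholded to masks) and
the continuous global-variable fit of the feature-correlation objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["QPSOConfig", "OptResult", "gaqpso_maximize"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QPSOConfig:
    """Engine settings.

    ``tol``/``patience`` implement the shared stopping rule: terminate
    after ``patience`` consecutive iterations in which the best fitness
    improves by less than ``tol``, or at ``max_iter``.
    """

    pop_size: int = 20
    max_iter: int = 200
    tol: float = 1e-4
    patience: int = 20
    beta_hi: float = 1.0
    beta_lo: float = 0.5
    pc_range: tuple = (0.6, 0.9)
    pm_range: tuple = (0.01, 0.1)

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class OptResult:
    """Best point found plus convergence diagnostics."""

    x: np.ndarray
    fun: float
    trace: list = field(default_factory=list)  # best-so-far per iteration
    n_iter: int = 0
    converged: bool = False


def _adaptive_rates(fitness: np.ndarray, cfg: QPSOConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual crossover/mutation probabilities, linear in fitness rank.

    rho = 0 for the best individual, 1 for the worst; worse individuals
    receive higher pc and pm (more disruption), better ones are protected.
    """
    order = np.argsort(np.argsort(-fitness))  # 0 = best
    n = fitness.size
    rho = order / max(n - 1, 1)
    pc = cfg.pc_range[0] + rho * (cfg.pc_range[1] - cfg.pc_range[0])
    pm = cfg.pm_range[0] + rho * (cfg.pm_range[1] - cfg.pm_range[0])
    return pc, pm


def gaqpso_maximize(
    objective,
    lower,
    upper,
    cfg: QPSOConfig,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> OptResult:
    """Maximize ``objective(x)`` over the box [lower, upper].

    Parameters
    ----------
    objective : callable
        Maps a 1-D position vector to a scalar fitness.
    init : ndarray, optional
        Rows used to seed part of the initial population; the remainder is
        drawn uniformly in the box.  Shrinking the box to a point returns
        that point.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ValueError("lower/upper bounds must be equal-length 1-D arrays")
    if np.any(lower > upper):
        raise ValueError("empty bounds: lower > upper")
    dim = lower.size
    span = upper - lower

    X = rng.uniform(lower, upper, size=(cfg.pop_size, dim))
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        k = min(len(init), cfg.pop_size)
        X[:k] = np.clip(init[:k], lower, upper)

    fit = np.array([objective(x) for x in X])
    pbest, pbest_fit = X.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest, gbest_fit = X[g].copy(), float(fit[g])

    trace = [gbest_fit]
    stall = 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        beta = cfg.beta_hi - (cfg.beta_hi - cfg.beta_lo) * (it - 1) / max(cfg.max_iter - 1, 1)
        mbest = pbest.mean(axis=0)

        phi = rng.random((cfg.pop_size, dim))
        attractor = phi * pbest + (1 - phi) * gbest
        u = rng.random((cfg.pop_size, dim))
        sign = np.where(rng.random((cfg.pop_size, dim)) < 0.5, -1.0, 1.0)
        X = attractor + sign * beta * np.abs(mbest - X) * np.log(1.0 / np.maximum(u, 1e-300))

        # genetic layer: arithmetic crossover + uniform mutation, adaptive rates
        pc, pm = _adaptive_rates(fit, cfg)
        partners = rng.integers(0, cfg.pop_size, size=cfg.pop_size)
        do_cx = rng.random(cfg.pop_size) < pc
        lam = rng.random((cfg.pop_size, dim))
        X = np.where(do_cx[:, None], lam * X + (1 - lam) * X[partners], X)
        mut = rng.random((cfg.pop_size, dim)) < pm[:, None]
        X = np.where(mut, rng.uniform(lower, upper, size=(cfg.pop_size, dim)), X)

        # degenerate population guard: reseed mutation on all but the best
        if np.all(np.ptp(X, axis=0) < 1e-12 * np.maximum(span, 1e-12)):
            logger.debug("degenerate population at iter %d; reseeding mutation", it)
            keep = int(np.argmax(fit))
            noise = rng.uniform(lower, upper, size=(cfg.pop_size, dim))
            blend = rng.random((cfg.pop_size, 1)) * 0.5
            X = (1 - blend) * X + blend * noise
            X[keep] = pbest[keep]

        X = np.clip(X, lower, upper)
        fit = np.array([objective(x) for x in X])

        improved = fit > pbest_fit
        pbest[improved] = X[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gain = pbest_fit[g] - gbest_fit
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        else:
            gain = 0.0
        trace.append(gbest_fit)

        stall = stall + 1 if gain < cfg.tol else 0
        if stall >= cfg.patience:
            return OptResult(x=gbest, fun=gbest_fit, trace=trace, n_iter=it, converged=True)

    return OptResult(x=gbest, fun=gbest_fit, trace=trace, n_iter=it, converged=False)
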