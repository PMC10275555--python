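"""Grey Wolf Optimizer for bounded continuous minimisation.

The population metaheuristic models a wolf pack: the three best solutions
found so far (alpha, beta, delta) steer every other wolf (the omegas).  At
each iteration the control scalar ``a`` decays linearly from ``a_init`` to
zero; for each wolf and each leader ``L`` in {alpha, beta, delta} a damped
attraction step is taken,

    A = 2*a*r1 - a,   C = 2*r2,
    D_L = |C * X_L - X|,   X_L' = X_L - A * D_L,

with fresh uniform random vectors ``r1``, ``r2`` per wolf and leader, and
the wolf moves to the mean of the three proposals, clamped to the search
box.  ``|A| < 1`` draws a wolf toward a leader ("the prey"), ``|A| > 1``
pushes it away, giving early exploration and late exploitation.  Leaders
are replaced only by strictly better solutions (elitism), so the
alpha-fitness trace is non-increasing.

An optional Gaussian perturbation of the omega wolves (probability and
scale configurable) is available but disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._exceptions import ValidationError

__all__ = ["GWOConfig", "GWOResult", "minimize"]


@dataclass(frozen=True)
class GWOConfig:
    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 20
    n_iters: int = 100
    n_restarts: int = 10
    a_init: float = 2.0
    seed: int = 0
    #: optional omega-wolf mutation: per-wolf probability and scale as a
    #: fraction of the box width; disabled unless ``enable_mutation``
    enable_mutation: bool = False
    mutation_prob: float = 0.25
    mutation_scale: float = 0.5

    def __post_init__(self) -> None:
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if self.pop_size < 4:
            raise ValidationError("pop_size must be >= 4 (three leaders + omegas)")
        if self.n_iters < 1 or self.n_restarts < 1:
            raise ValidationError("n_iters and n_restarts must be >= 1")
        for lo, hi in bounds:
            if not lo < hi:
                raise ValidationError(f"invalid bound ({lo}, {hi})")

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass(frozen=True)
class GWOResult:
    best_position: np.ndarray
    best_fitness: float
    #: alpha fitness after each iteration, for the restart that won
    trace: np.ndarray
    n_evaluations: int
    seed: int

    def write_trace(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("iter\talpha_fitness\n")
            for i, value in enumerate(self.trace):
                fh.write(f"{i}\t{value!r}\n")


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    fitness = np.empty(X.shape[0])
    for i, x in enumerate(X):
        value = float(objective(x))
        if not np.isfinite(value):
            raise ValidationError(
                f"objective returned non-finite value {value} at position {x.tolist()}"
            )
        fitness[i] = value
    return fitness


def _run_pack(
    objective, cfg: GWOConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float, np.ndarray, int]:
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    X = rng.uniform(lo, hi, size=(cfg.pop_size, cfg.dim))
    fitness = _evaluate(objective, X)
    n_evals = cfg.pop_size
    order = np.argsort(fitness, kind="stable")[:3]
    leaders = X[order].copy()
    leader_fit = fitness[order].copy()
    trace = np.empty(cfg.n_iters)
    for it in range(cfg.n_iters):
        a = cfg.a_init * (1.0 - it / cfg.n_iters)
        proposals = np.empty((3,) + X.shape)
        for k in range(3):
            r1 = rng.random(X.shape)
            r2 = rng.random(X.shape)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            D = np.abs(C * leaders[k] - X)
            proposals[k] = leaders[k] - A * D
        X = proposals.mean(axis=0)
        if cfg.enable_mutation:
            mutate = rng.random(cfg.pop_size) < cfg.mutation_prob
            noise = rng.normal(0.0, cfg.mutation_scale, X.shape) * (hi - lo)
            X[mutate] += noise[mutate]
        np.clip(X, lo, hi, out=X)
        fitness = _evaluate(objective, X)
        n_evals += cfg.pop_size
        for i in np.argsort(fitness, kind="stable"):
            f = fitness[i]
            if f < leader_fit[0]:
                leaders = np.vstack([X[i], leaders[:2]])
                leader_fit = np.concatenate([[f], leader_fit[:2]])
            elif f < leader_fit[1] and not np.array_equal(X[i], leaders[0]):
                leaders = np.vstack([leaders[:1], X[i][None], leaders[1:2]])
                leader_fit = np.concatenate([leader_fit[:1], [f], leader_fit[1:2]])
            elif f < leader_fit[2] and not np.array_equal(X[i], leaders[1]):
                leaders[2] = X[i]
                leader_fit[2] = f
        trace[it] = leader_fit[0]
    return leaders[0], float(leader_fit[0]), trace, n_evals


def minimize(
    objective: Callable[[np.ndarray], float], cfg: GWOConfig
) -> GWOResult:
    """Minimise ``objective`` over the configured box.

    The pack search is restarted ``n_restarts`` times from independent
    seeded populations; the best alpha over all restarts is returned,
    together with the alpha-fitness trace of the winning restart.  The
    whole procedure is a pure function of ``cfg`` (including its seed).
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    total_evals = 0
    for seq in seeds:
        rng = np.random.default_rng(seq)
        position, fit, trace, n_evals = _run_pack(objective, cfg, rng)
        total_evals += n_evals
        if best is None or fit < best[0]:
            best = (fit, position, trace)
    fit, position, trace = best
    return GWOResult(
        best_position=position,
        best_fitness=fit,
        trace=trace,
        n_evaluations=total_evals,
        seed=cfg.seed,
    )
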