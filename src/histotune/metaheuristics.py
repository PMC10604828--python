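"""Population-based metaheuristics over the unit hypercube.

Two optimizers are provided, both maximizing a fitness callable over
solution vectors in ``[0, 1]^D``:

* **Aquila Optimizer (AO)** — four hunting-inspired moves.  While
  ``t <= (2/3) T`` the *exploration* moves run: expanded exploration pulls
  candidates between the best solution and the population mean, narrowed
  exploration combines a Levy flight around the best solution with a spiral
  walk.  Afterwards the *exploitation* moves run: expanded exploitation
  perturbs around the best/mean difference, narrowed exploitation follows a
  quality-function weighted attack on the best solution.  Within each phase
  the two moves are chosen by a fair coin per member.

* **Artificial Gorilla Troops Optimizer (GTO)** — per iteration an
  exploration sweep (migration to an unknown location with probability
  ``p``, a move toward a random other gorilla, or a position-aware
  dimension mix) followed by an exploitation sweep (follow the silverback
  when ``C >= W``, otherwise competition for adult females around the
  silverback).

Both use greedy acceptance (a candidate replaces a member only when its
fitness improves) and clip-to-bounds repair, so the best-so-far fitness is
monotone non-decreasing and all positions stay inside the hypercube.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma

from .search_space import (
    DecodedConfiguration,
    SearchSpace,
    clip_to_bounds,
    decode_solution,
    init_population,
)

__all__ = [
    "Population",
    "OptimizerState",
    "AOParams",
    "GTOParams",
    "EvaluationError",
    "levy_sigma",
    "levy_step",
    "rank_population",
    "ao_update",
    "gto_update",
    "optimize_vectors",
    "run_optimizer",
    "write_history_csv",
]


class EvaluationError(RuntimeError):
    """The objective failed on a member; carries the decoded configuration."""

    def __init__(self, message: str, configuration=None):
        super().__init__(message)
        self.configuration = configuration


@dataclass
class Population:
    """N solution vectors with fitness scores (higher is better)."""

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    evaluated: np.ndarray  # (N,) bool

    @classmethod
    def from_positions(cls, positions: np.ndarray) -> "Population":
        n = positions.shape[0]
        return cls(
            positions=np.array(positions, dtype=float),
            fitness=np.full(n, -np.inf),
            evaluated=np.zeros(n, dtype=bool),
        )

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def require_evaluated(self) -> None:
        if not self.evaluated.all():
            raise EvaluationError("population must be fully evaluated before updating")

    @property
    def best(self) -> tuple[np.ndarray, float]:
        i = int(np.argmax(self.fitness))
        return self.positions[i].copy(), float(self.fitness[i])

    @property
    def worst(self) -> tuple[np.ndarray, float]:
        i = int(np.argmin(self.fitness))
        return self.positions[i].copy(), float(self.fitness[i])


@dataclass
class OptimizerState:
    """Loop bookkeeping shared by both algorithms."""

    t: int
    t_max: int
    rng: np.random.Generator
    best_position: np.ndarray | None = None
    best_fitness: float = -np.inf
    n_evaluations: int = 0
    counters: dict = field(default_factory=lambda: {"exploration": 0, "exploitation": 0})

    def track(self, population: Population) -> None:
        pos, fit = population.best
        if fit > self.best_fitness:
            self.best_fitness = fit
            self.best_position = pos


@dataclass(frozen=True)
class AOParams:
    """Aquila Optimizer constants (the published defaults)."""

    alpha: float = 0.1
    delta: float = 0.1
    levy_beta: float = 1.5
    levy_s: float = 0.01
    spiral_U: float = 0.00565
    spiral_omega: float = 0.005
    r1_base: int = 10  # search-cycle count, an integer in [1, 20]

    def __post_init__(self) -> None:
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must lie in (0, 2]")
        if not 1 <= self.r1_base <= 20:
            raise ValueError("r1_base must be an integer in [1, 20]")


@dataclass(frozen=True)
class GTOParams:
    """Gorilla Troops Optimizer constants (the published defaults)."""

    p: float = 0.03  # migration probability
    W: float = 0.8  # exploitation switch threshold
    beta: float = 3.0  # violence coefficient

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def levy_sigma(beta: float) -> float:
    """Mantegna scale constant sigma for a Levy stability index ``beta``."""
    num = gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(D: int, beta: float = 1.5, s: float = 0.01, rng: np.random.Generator | None = None) -> np.ndarray:
    """Heavy-tailed Levy flight step of dimension ``D`` (Mantegna algorithm).

    Each component is ``s * u * sigma / |v|**(1/beta)`` with ``u, v``
    standard normal draws.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    sigma = levy_sigma(beta)
    u = rng.standard_normal(D)
    v = rng.standard_normal(D)
    return s * u * sigma / np.abs(v) ** (1.0 / beta)


def rank_population(population: Population) -> Population:
    """Stable sort, best fitness first."""
    population.require_evaluated()
    order = np.argsort(-population.fitness, kind="stable")
    return Population(
        positions=population.positions[order],
        fitness=population.fitness[order],
        evaluated=population.evaluated[order],
    )


def _greedy_accept(population, i, candidate, objective, state) -> None:
    candidate = clip_to_bounds(candidate)
    fit = float(objective(candidate))
    state.n_evaluations += 1
    if fit > population.fitness[i]:
        population.positions[i] = candidate
        population.fitness[i] = fit


def ao_update(
    population: Population,
    state: OptimizerState,
    params: AOParams,
    objective: Callable[[np.ndarray], float],
) -> Population:
    """One Aquila Optimizer sweep (phase switch at ``t <= (2/3) t_max``)."""
    population.require_evaluated()
    rng = state.rng
    t, T = state.t, state.t_max
    D = population.dim
    x_best, _ = population.best
    exploring = t <= (2.0 / 3.0) * T

    for i in range(population.size):
        x_mean = population.positions.mean(axis=0)
        x = population.positions[i]
        if exploring:
            state.counters["exploration"] += 1
            if rng.random() < 0.5:
                # expanded exploration: high soar with vertical stoop
                cand = x_best * (1.0 - t / T) + (x_mean - x_best * rng.random())
            else:
                # narrowed exploration: contour flight with short glide;
                # Levy flight about the best plus a spiral walk
                x_rand = population.positions[int(rng.integers(population.size))]
                d1 = np.arange(1, D + 1, dtype=float)
                r = params.r1_base + params.spiral_U * d1
                theta = -params.spiral_omega * d1 + 3.0 * math.pi / 2.0
                xs = r * np.sin(theta)
                ys = r * np.cos(theta)
                cand = (
                    x_best * levy_step(D, params.levy_beta, params.levy_s, rng)
                    + x_rand
                    + (ys - xs) * rng.random()
                )
        else:
            state.counters["exploitation"] += 1
            if rng.random() < 0.5:
                # expanded exploitation: low soar with slow descent
                cand = (
                    (x_best - x_mean) * params.alpha
                    - rng.random()
                    + ((1.0 - 0.0) * rng.random() + 0.0) * params.delta
                )
                cand = np.broadcast_to(cand, (D,)) if np.ndim(cand) == 0 else cand
            else:
                # narrowed exploitation: walk-and-grab attack
                rnd = rng.random()
                # degenerate single-iteration run: the quality function is 1
                qf = 1.0 if T == 1 else t ** ((2.0 * rng.random() - 1.0) / (1.0 - T) ** 2)
                g1 = 2.0 * rng.random() - 1.0
                g2 = 2.0 * (1.0 - t / T)
                cand = (
                    qf * x_best
                    - g1 * x * rnd
                    - g2 * levy_step(D, params.levy_beta, params.levy_s, rng)
                    + rnd * g1
                )
        _greedy_accept(population, i, cand, objective, state)
        x_best, _ = population.best
    state.track(population)
    return population


def gto_update(
    population: Population,
    state: OptimizerState,
    params: GTOParams,
    objective: Callable[[np.ndarray], float],
) -> Population:
    """One Gorilla Troops sweep: exploration then exploitation."""
    population.require_evaluated()
    rng = state.rng
    t, T = state.t, state.t_max
    D = population.dim
    N = population.size

    F = math.cos(2.0 * rng.random()) + 1.0
    C = F * (1.0 - t / T)
    l = rng.uniform(-1.0, 1.0)
    L = C * l

    # -- exploration ---------------------------------------------------
    state.counters["exploration"] += N
    for i in range(N):
        x = population.positions[i]
        if rng.random() < params.p:
            # migration to an unknown location
            cand = rng.random(D)
        elif rng.random() >= 0.5:
            # move toward another gorilla
            z = rng.uniform(-C, C, size=D)
            h = z * x
            x_rand = population.positions[int(rng.integers(N))]
            cand = L * h + (rng.random() - C) * x_rand
        else:
            # dimension mix around a random position
            x_rand = population.positions[int(rng.integers(N))]
            r3 = rng.random()
            cand = x - L * (L * (x - x_rand) + r3 * (x - x_rand))
        _greedy_accept(population, i, cand, objective, state)

    # -- exploitation ---------------------------------------------------
    state.counters["exploitation"] += N
    x_silverback, _ = population.best
    for i in range(N):
        x = population.positions[i]
        if C >= params.W:
            # follow the silverback
            g = 2.0 ** L
            M = (np.abs(population.positions.mean(axis=0)) ** g) ** (1.0 / g)
            cand = L * M * (x - x_silverback) + x
        else:
            # competition for adult females
            q = 2.0 * rng.random() - 1.0
            if rng.random() < 0.5:
                A = params.beta * rng.standard_normal(D)
            else:
                A = params.beta * rng.standard_normal()
            cand = x_silverback - (x_silverback * q - x * q) * A
        _greedy_accept(population, i, cand, objective, state)
        x_silverback, _ = population.best
    state.track(population)
    return population


_UPDATES = {"AO": (ao_update, AOParams), "GTO": (gto_update, GTOParams)}


def optimize_vectors(
    objective: Callable[[np.ndarray], float],
    D: int,
    n_solutions: int,
    t_max: int,
    algorithm: str = "AO",
    seed: int = 0,
    params=None,
) -> tuple[np.ndarray, float, list[float], OptimizerState]:
    """Core loop over raw vectors in ``[0, 1]^D``.

    Returns (best vector, best fitness, per-iteration best-fitness history,
    final state).  The history has length ``t_max`` and is non-decreasing.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    algorithm = algorithm.upper()
    if algorithm not in _UPDATES:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose AO or GTO")
    update, params_cls = _UPDATES[algorithm]
    if params is None:
        params = params_cls()

    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n_solutions, D))
    pop = Population.from_positions(positions)
    state = OptimizerState(t=0, t_max=t_max, rng=rng)
    for i in range(pop.size):
        pop.fitness[i] = float(objective(pop.positions[i]))
        pop.evaluated[i] = True
        state.n_evaluations += 1
    state.track(pop)

    history: list[float] = []
    for t in range(1, t_max + 1):
        state.t = t
        pop = rank_population(pop)
        pop = update(pop, state, params, objective)
        history.append(state.best_fitness)
    return state.best_position, state.best_fitness, history, state


def run_optimizer(
    objective: Callable[[DecodedConfiguration], float],
    space: SearchSpace,
    n_solutions: int,
    t_max: int,
    algorithm: str = "AO",
    seed: int = 0,
    params=None,
) -> tuple[DecodedConfiguration, float, list[float]]:
    """Optimize a fitness callable defined on decoded configurations.

    Initializes a uniform population once, then for ``t_max`` iterations
    evaluates members through decode -> objective, ranks, and updates with
    the chosen algorithm.  Objective failures are re-raised as
    :class:`EvaluationError` carrying the decoded configuration.
    """
    if n_solutions < 2:
        raise ValueError("a population needs at least 2 solutions")

    def f(vec: np.ndarray) -> float:
        config = decode_solution(vec, space)
        try:
            return float(objective(config))
        except EvaluationError:
            raise
        except Exception as exc:  # noqa: BLE001 - contract: tag with the config
            raise EvaluationError(f"objective failed: {exc}", configuration=config) from exc

    best_vec, best_fit, history, _ = optimize_vectors(
        f, space.D, n_solutions, t_max, algorithm=algorithm, seed=seed, params=params
    )
    return decode_solution(best_vec, space), best_fit, history


def write_history_csv(path, history: Sequence[float], mean_fitness: Sequence[float] | None = None,
                      best_config: DecodedConfiguration | None = None) -> None:
    """Optimization history as CSV (iteration, best fitness, mean fitness, best config JSON)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "best_fitness", "mean_fitness", "best_configuration"])
        cfg = best_config.to_json() if best_config is not None else ""
        for i, b in enumerate(history, start=1):
            m = "" if mean_fitness is None else mean_fitness[i - 1]
            w.writerow([i, b, m, cfg if i == len(history) else ""])
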