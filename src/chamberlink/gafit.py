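"""Genetic-algorithm parameter estimation with an L2-norm objective.

Each generation of 100 candidates is built from the previous one as:

* the 10 lowest-objective candidates carried over unchanged (elitism; their
  objectives are cached, not re-evaluated),
* 9 candidates formed by averaging the best candidate with each of ranks
  2-10 (per-parameter arithmetic mean; log-scaled parameters are averaged in
  log space),
* 81 fresh uniform samples within the bounds.

The run stops once the relative improvement of the best objective has stayed
below ``stall_tolerance`` for 10 consecutive generations, or at
``max_generations``.  An optional structure search treats the number of delay
equations as an integer gene (uniformly sampled for fresh candidates,
rounded averages mutated by +/-1 with probability 1/2).

Runs are reproducible: the seed is mandatory and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterBounds",
    "FitProblem",
    "FitResult",
    "objective_l2",
    "ga_generation",
    "fit",
]

POPULATION_SIZE = 100
N_ELITE = 10
N_AVERAGED = 9
N_FRESH = POPULATION_SIZE - N_ELITE - N_AVERAGED
STALL_GENERATIONS = 10


@dataclass(frozen=True)
class ParameterBounds:
    """Named (lower, upper) bounds with per-parameter linear/log scale hints."""

    lower: Mapping[str, float]
    upper: Mapping[str, float]
    scale: Mapping[str, str] | None = None      # "linear" (default) | "log"

    def __post_init__(self) -> None:
        if set(self.lower) != set(self.upper):
            raise ValueError("lower and upper bounds must name the same parameters")
        for name in self.lower:
            lo, hi = self.lower[name], self.upper[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
            if self.scale_of(name) == "log" and lo <= 0:
                raise ValueError(f"log-scaled parameter {name!r} needs positive bounds")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.lower))

    def scale_of(self, name: str) -> str:
        if self.scale and name in self.scale:
            if self.scale[name] not in ("linear", "log"):
                raise ValueError(f"unknown scale {self.scale[name]!r}")
            return self.scale[name]
        return "linear"

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name in self.names:
            lo, hi = self.lower[name], self.upper[name]
            if self.scale_of(name) == "log":
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[name] = float(rng.uniform(lo, hi))
        return out

    def average(self, a: Mapping[str, float], b: Mapping[str, float]) -> dict[str, float]:
        out = {}
        for name in self.names:
            if self.scale_of(name) == "log":
                out[name] = float(np.exp((np.log(a[name]) + np.log(b[name])) / 2.0))
            else:
                out[name] = float((a[name] + b[name]) / 2.0)
        return out


@dataclass
class FitProblem:
    """A simulator, the observed series it must match, and the search space.

    ``simulator(params)`` (or ``simulator(params, structure)`` when
    ``structure_search`` is set) returns the predicted series on the observed
    time grid.  ``structure_search`` is an inclusive (lo, hi) range for the
    integer number of delay equations.
    """

    simulator: Callable[..., np.ndarray]
    observed: np.ndarray
    bounds: ParameterBounds
    structure_search: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.structure_search is not None:
            lo, hi = self.structure_search
            if not (isinstance(lo, int) and isinstance(hi, int) and 1 <= lo <= hi):
                raise ValueError("structure_search must be an integer range (lo, hi), lo >= 1")


@dataclass
class FitResult:
    best_parameters: dict[str, float]
    best_objective: float
    best_structure: int | None
    objective_trace: list[float]
    converged: bool
    generations: int
    seed: int
    n_simulator_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "best_parameters": self.best_parameters,
            "best_objective": self.best_objective,
            "best_structure": self.best_structure,
            "objective_trace": self.objective_trace,
            "converged": self.converged,
            "generations": self.generations,
            "seed": self.seed,
            "n_simulator_failures": self.n_simulator_failures,
        }


def objective_l2(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Euclidean norm of the residual vector (flattened across traces)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    return float(np.linalg.norm((predicted - observed).ravel()))


def _mutate_structure(n: int, lo: int, hi: int, rng: np.random.Generator) -> int:
    if rng.random() < 0.5:
        n += int(rng.choice([-1, 1]))
    return int(np.clip(n, lo, hi))


def ga_generation(population: Sequence[dict], objectives: Sequence[float],
                  bounds: ParameterBounds, rng: np.random.Generator,
                  structure_search: tuple[int, int] | None = None
                  ) -> tuple[list[dict], np.ndarray]:
    """One selection/recombination step; returns (next population, carried flags).

    ``carried`` marks candidates whose objective is already known (the elite),
    so the caller can skip re-simulation.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required for reproducibility")
    if len(population) != POPULATION_SIZE or len(objectives) != POPULATION_SIZE:
        raise ValueError(f"population and objectives must have size {POPULATION_SIZE}")
    order = np.argsort(objectives, kind="stable")
    ranked = [population[i] for i in order]
    elite = [dict(c) for c in ranked[:N_ELITE]]
    best = ranked[0]
    nxt: list[dict] = list(elite)
    for partner in ranked[1:1 + N_AVERAGED]:
        child = bounds.average(best, partner)
        if structure_search is not None:
            n = int(round((best["__structure__"] + partner["__structure__"]) / 2.0))
            child["__structure__"] = _mutate_structure(n, *structure_search, rng=rng)
        nxt.append(child)
    for _ in range(N_FRESH):
        cand = bounds.sample(rng)
        if structure_search is not None:
            lo, hi = structure_search
            cand["__structure__"] = int(rng.integers(lo, hi + 1))
        nxt.append(cand)
    carried = np.zeros(POPULATION_SIZE, dtype=bool)
    carried[:N_ELITE] = True
    return nxt, carried


def fit(problem: FitProblem, rng_seed: int, max_generations: int = 200,
        stall_tolerance: float = 1e-4) -> FitResult:
    """Run the genetic algorithm until the objective stalls for 10 generations."""
    rng = np.random.default_rng(rng_seed)
    bounds = problem.bounds
    ss = problem.structure_search
    n_failures = 0

    def evaluate(cand: dict) -> float:
        nonlocal n_failures
        params = {k: v for k, v in cand.items() if k != "__structure__"}
        try:
            if ss is not None:
                pred = problem.simulator(params, int(cand["__structure__"]))
            else:
                pred = problem.simulator(params)
            return objective_l2(pred, problem.observed)
        except Exception:
            n_failures += 1
            return float("inf")

    population = []
    for _ in range(POPULATION_SIZE):
        cand = bounds.sample(rng)
        if ss is not None:
            cand["__structure__"] = int(rng.integers(ss[0], ss[1] + 1))
        population.append(cand)
    objectives = np.array([evaluate(c) for c in population])

    trace: list[float] = []
    best_obj = float(np.min(objectives))
    stall = 0
    gen = 0
    converged = False
    while gen < max_generations:
        gen += 1
        trace.append(best_obj)
        population, carried = ga_generation(population, objectives, bounds, rng,
                                            structure_search=ss)
        new_obj = np.empty(POPULATION_SIZE)
        prev_sorted = np.sort(objectives, kind="stable")
        new_obj[:N_ELITE] = prev_sorted[:N_ELITE]       # cached elite objectives
        for i in range(N_ELITE, POPULATION_SIZE):
            new_obj[i] = evaluate(population[i])
        objectives = new_obj
        new_best = float(np.min(objectives))
        rel_change = (best_obj - new_best) / best_obj if best_obj > 0 else 0.0
        if not np.isfinite(best_obj):
            rel_change = np.inf if np.isfinite(new_best) else 0.0
        best_obj = min(best_obj, new_best)
        if rel_change < stall_tolerance:
            stall += 1
        else:
            stall = 0
        if stall >= STALL_GENERATIONS:
            converged = True
            break
    trace.append(best_obj)

    k = int(np.argmin(objectives))
    winner = population[k]
    best_params = {name: winner[name] for name in bounds.names}
    best_structure = int(winner["__structure__"]) if ss is not None else None
    return FitResult(best_parameters=best_params, best_objective=float(objectives[k]),
                     best_structure=best_structure, objective_trace=trace,
                     converged=converged, generations=gen, seed=rng_seed,
                     n_simulator_failures=n_failures)
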