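"""Differential Evolution wrapper feature selection.

Classic DE/rand/1/bin on a continuous relaxation: each candidate lives in the
unit hypercube and its feature subset is the coordinates at or above 0.5.
Mutation builds a donor vector ``v = x_r1 + F (x_r2 - x_r3)`` from three
distinct random population members, binomial crossover mixes donor and target
coordinates, and greedy selection keeps whichever of trial and target scores
higher on the wrapper fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._base import BaseWrapperSelector, score_of
from .data import ClinicalDataset, SelectionMask
from .fitness import FitnessConfig, FitnessResult, binarize_position

__all__ = ["DEConfig", "Candidate", "de_generation_step", "run_de", "DEFeatureSelector"]


@dataclass(frozen=True)
class DEConfig:
    population_size: int = 100
    max_iterations: int = 20
    F: float = 0.5
    CR: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("DE needs at least 4 candidates")
        if not 0 < self.CR <= 1:
            raise ValueError("CR must be in (0, 1]")
        if self.F <= 0:
            raise ValueError("F must be positive")


@dataclass
class Candidate:
    position: np.ndarray
    mask: SelectionMask = field(default=None)
    fitness: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mask is None:
            self.mask = binarize_position(self.position)


def _evaluated(position: np.ndarray, fitness) -> Candidate:
    cand = Candidate(np.clip(position, 0.0, 1.0))
    cand.fitness = score_of(fitness, cand.mask)
    return cand


def de_generation_step(population, config: DEConfig, fitness, rng=None):
    """One DE generation: mutate, crossover, and greedily select survivors.

    Ties between trial and target go to the trial, which lets the population
    drift across fitness plateaus of the binarized encoding.
    """
    if any(c.fitness is None for c in population):
        raise RuntimeError("population must be evaluated before stepping")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_pop = len(population)
    dim = population[0].position.shape[0]
    survivors = []
    for i, target in enumerate(population):
        choices = [j for j in range(n_pop) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        mutant = population[r1].position + config.F * (
            population[r2].position - population[r3].position
        )
        mutant = np.clip(mutant, 0.0, 1.0)
        cross = rng.random(dim) < config.CR
        cross[rng.integers(dim)] = True  # j_rand: at least one donor coordinate
        trial = np.where(cross, mutant, target.position)
        trial_cand = _evaluated(trial, fitness)
        survivors.append(trial_cand if trial_cand.fitness >= target.fitness else target)
    return survivors


class DEFeatureSelector(BaseWrapperSelector):
    """Differential-Evolution feature selector with the sklearn selector API."""

    def __init__(self, population_size: int = 100, max_iterations: int = 20,
                 F: float = 0.5, CR: float = 0.9, fitness=None,
                 fitness_config: FitnessConfig | None = None, random_state: int = 0):
        super().__init__(fitness=fitness, fitness_config=fitness_config,
                         random_state=random_state)
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.F = F
        self.CR = CR

    def _optimize(self, n_features, fitness, rng):
        config = DEConfig(self.population_size, self.max_iterations, self.F,
                          self.CR, self.random_state)
        population = [
            _evaluated(rng.random(n_features), fitness)
            for _ in range(config.population_size)
        ]
        best = max(population, key=lambda c: c.fitness)
        trace = [best.fitness]
        for _ in range(config.max_iterations):
            population = de_generation_step(population, config, fitness, rng)
            gen_best = max(population, key=lambda c: c.fitness)
            if gen_best.fitness > best.fitness:
                best = gen_best
            trace.append(best.fitness)
        return best.mask, best.fitness, trace


def run_de(dataset: ClinicalDataset, config: DEConfig | None = None,
           fitness=None) -> FitnessResult:
    """Run DE selection on a preprocessed dataset; return the best mask found."""
    config = config or DEConfig()
    selector = DEFeatureSelector(
        population_size=config.population_size, max_iterations=config.max_iterations,
        F=config.F, CR=config.CR, fitness=fitness, random_state=config.seed,
    )
    selector.fit(dataset.X, dataset.y)
    mask = selector.support_mask_.astype(int)
    return FitnessResult(mask, selector.best_fitness_, int(mask.sum()))
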