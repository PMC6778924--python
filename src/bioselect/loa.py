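"""Lion Optimization Algorithm wrapper feature selection.

A single pride of resident lions hunts a virtual prey placed at the centroid
of the hunters: wing membership (left/centre/right) decides whether a hunter
jumps toward the prey directly or through the reflected point ``2·PREY − x``,
and every fitness improvement lets the prey escape proportionally to the
improvement.  Nomad lions roam by coordinate-wise random resets whose
probability grows with their cost gap to the best nomad, and random pride
pairs mate through a Gaussian β-blend.  Offspring and successful nomads
displace the worst prides, so the pride never loses its best solutions during
replacement.  Positions live in the unit hypercube; the feature subset is the
coordinates at or above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._base import BaseWrapperSelector, score_of
from .data import ClinicalDataset, SelectionMask
from .fitness import FitnessConfig, FitnessResult, binarize_position

__all__ = [
    "LOAConfig",
    "Lion",
    "hunt_phase",
    "nomad_roam_phase",
    "mating_phase",
    "run_loa",
    "LOAFeatureSelector",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LOAConfig:
    n_prides: int = 20
    n_nomads: int = 40
    n_center_wing: int = 6
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.n_prides, self.n_nomads, self.n_center_wing) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_center_wing > self.n_prides:
            raise ValueError("centre wing cannot exceed the pride count")


@dataclass
class Lion:
    position: np.ndarray
    fitness: float | None = None
    role: str = "pride"  # pride | nomad
    wing: str = "none"  # left | centre | right | none
    mask: SelectionMask = field(default=None)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mask is None:
            self.mask = binarize_position(self.position)
        if (self.role == "nomad") != (self.wing == "none") and self.role == "nomad":
            raise ValueError("nomads carry no wing")


def _make_lion(position, fitness, role="pride", wing="none") -> Lion:
    lion = Lion(np.clip(position, 0.0, 1.0), role=role, wing=wing)
    lion.fitness = score_of(fitness, lion.mask)
    return lion


def _rand_between(rng, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Coordinate-wise uniform draw on [min(a,b), max(a,b)]."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return lo + rng.random(a.shape) * (hi - lo)


def hunt_phase(prides: list[Lion], fitness, config: LOAConfig, rng=None) -> list[Lion]:
    """Encircle a virtual prey: wing assignment, jumps, and prey escapes.

    The prey starts at the hunters' centroid; left/right wings jump through
    the reflected point ``2·PREY − x`` while the centre wing jumps between its
    own position and the prey.  Each fitness improvement moves the prey away
    from the successful hunter proportionally to the relative improvement.
    """
    if not prides:
        raise ValueError("empty pride list")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    order = sorted(range(len(prides)), key=lambda i: -prides[i].fitness)
    wings = {}
    for rank, idx in enumerate(order):
        if rank < config.n_center_wing:
            wings[idx] = "centre"
        else:
            wings[idx] = "left" if (rank - config.n_center_wing) % 2 == 0 else "right"
    prey = np.mean([lion.position for lion in prides], axis=0)
    out: list[Lion] = [None] * len(prides)
    for idx in order:
        hunter = prides[idx]
        if wings[idx] == "centre":
            new_pos = _rand_between(rng, hunter.position, prey)
        else:
            new_pos = _rand_between(rng, 2.0 * prey - hunter.position, prey)
        moved = _make_lion(new_pos, fitness, role="pride", wing=wings[idx])
        if moved.fitness > hunter.fitness:
            pi = (moved.fitness - hunter.fitness) / max(hunter.fitness, _EPS)
            prey = np.clip(prey + rng.random() * pi * (prey - moved.position), 0.0, 1.0)
        out[idx] = moved
    return out


def nomad_roam_phase(nomads: list[Lion], fitness, rng=None, seed: int = 0) -> list[Lion]:
    """Adaptive roaming: resample coordinates with probability tied to cost gap.

    cost = 1 − fitness; the best nomad resamples each coordinate with
    probability 0.1, worse nomads with up to 0.6.
    """
    if not nomads:
        raise ValueError("empty nomad list")
    rng = np.random.default_rng(seed) if rng is None else rng
    costs = np.array([1.0 - lion.fitness for lion in nomads])
    best_cost = costs.min()
    out = []
    for lion, cost in zip(nomads, costs):
        pr = 0.1 + min(0.5, (cost - best_cost) / max(best_cost, _EPS))
        keep = rng.random(lion.position.shape) > pr
        new_pos = np.where(keep, lion.position, rng.random(lion.position.shape))
        out.append(_make_lion(new_pos, fitness, role="nomad"))
    return out


def mating_phase(parent1: Lion, parent2: Lion, rng=None, fitness=None,
                 beta_mean: float = 0.5, beta_sd: float = 0.1,
                 seed: int = 0) -> tuple[Lion, Lion]:
    """β-blend mating: two offspring that mirror each other around the midpoint."""
    if parent1 is parent2:
        raise ValueError("mating requires two distinct lions")
    rng = np.random.default_rng(seed) if rng is None else rng
    beta = rng.normal(beta_mean, beta_sd)
    off1 = beta * parent1.position + (1.0 - beta) * parent2.position
    off2 = (1.0 - beta) * parent1.position + beta * parent2.position
    if fitness is None:
        return Lion(np.clip(off1, 0, 1)), Lion(np.clip(off2, 0, 1))
    return _make_lion(off1, fitness), _make_lion(off2, fitness)


class LOAFeatureSelector(BaseWrapperSelector):
    """Lion-Optimization feature selector with the sklearn selector API."""

    def __init__(self, n_prides: int = 20, n_nomads: int = 40, n_center_wing: int = 6,
                 max_iterations: int = 100, fitness=None,
                 fitness_config: FitnessConfig | None = None, random_state: int = 0):
        super().__init__(fitness=fitness, fitness_config=fitness_config,
                         random_state=random_state)
        self.n_prides = n_prides
        self.n_nomads = n_nomads
        self.n_center_wing = n_center_wing
        self.max_iterations = max_iterations

    def _optimize(self, n_features, fitness, rng):
        config = LOAConfig(self.n_prides, self.n_nomads, self.n_center_wing,
                           self.max_iterations, self.random_state)
        prides = [_make_lion(rng.random(n_features), fitness)
                  for _ in range(config.n_prides)]
        nomads = [_make_lion(rng.random(n_features), fitness, role="nomad")
                  for _ in range(config.n_nomads)]
        best = max(prides, key=lambda l: l.fitness)
        trace = [best.fitness]
        for _ in range(config.max_iterations):
            prides = hunt_phase(prides, fitness, config, rng)
            nomads = nomad_roam_phase(nomads, fitness, rng)
            pairing = rng.permutation(config.n_prides)
            offspring: list[Lion] = []
            for a, b in zip(pairing[0::2], pairing[1::2]):
                offspring.extend(mating_phase(prides[a], prides[b], rng, fitness))
            # replacement: better offspring/nomads displace the worst pride
            for child in offspring:
                worst = min(range(len(prides)), key=lambda i: prides[i].fitness)
                if child.fitness > prides[worst].fitness:
                    child.role, child.wing = "pride", "none"
                    prides[worst] = child
            for i, nomad in enumerate(nomads):
                worst = min(range(len(prides)), key=lambda i: prides[i].fitness)
                if nomad.fitness > prides[worst].fitness:
                    displaced = prides[worst]
                    promoted = Lion(nomad.position.copy(), fitness=nomad.fitness)
                    prides[worst] = promoted
                    displaced.role, displaced.wing = "nomad", "none"
                    nomads[i] = displaced
            gen_best = max(prides, key=lambda l: l.fitness)
            if gen_best.fitness > best.fitness:
                best = gen_best
            trace.append(best.fitness)
        return best.mask, best.fitness, trace


def run_loa(dataset: ClinicalDataset, config: LOAConfig | None = None,
            fitness=None) -> FitnessResult:
    """Run LOA selection on a preprocessed dataset; return the best mask found."""
    config = config or LOAConfig()
    selector = LOAFeatureSelector(
        n_prides=config.n_prides, n_nomads=config.n_nomads,
        n_center_wing=config.n_center_wing, max_iterations=config.max_iterations,
        fitness=fitness, random_state=config.seed,
    )
    selector.fit(dataset.X, dataset.y)
    mask = selector.support_mask_.astype(int)
    return FitnessResult(mask, selector.best_fitness_, int(mask.sum()))
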