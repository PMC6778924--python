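"""Glowworm Swarm Optimization wrapper feature selection.

Each glowworm carries a luciferin level that decays by a factor (1 − ρ) and
grows with the fitness of its current position, l ← (1 − ρ)·l + γ·J.  A worm
moves a fixed step s toward one probabilistically chosen brighter neighbour
inside its adaptive sensing range, and the range expands or shrinks to track
a desired neighbour count n_t.  The reported feature subset is the mask of
the maximum-luciferin worm (coordinates at or above 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._base import BaseWrapperSelector, score_of
from .data import ClinicalDataset, SelectionMask
from .fitness import FitnessConfig, FitnessResult, binarize_position

__all__ = [
    "GSOConfig",
    "Glowworm",
    "luciferin_update",
    "neighbor_probabilities",
    "glowworm_step",
    "run_gso",
    "GSOFeatureSelector",
]

_RANGE_FLOOR = 1e-6  # a zero sensing range would freeze a worm permanently


@dataclass(frozen=True)
class GSOConfig:
    n_glowworms: int = 50
    max_iterations: int = 100
    rho: float = 0.4       # luciferin decay
    gamma: float = 0.6     # luciferin enhancement
    beta: float = 0.08     # range-update gain
    n_t: int = 5           # desired neighbour count
    s: float = 0.03        # step size
    l0: float = 5.0        # initial luciferin
    r0: float | None = None  # initial sensing range (default 0.5*sqrt(n))
    rs: float | None = None  # maximum sensor range (default 0.5*sqrt(n))
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.gamma <= 0 or self.s <= 0:
            raise ValueError("gamma and s must be positive")
        if self.r0 is not None and self.rs is not None and not 0 < self.r0 <= self.rs:
            raise ValueError("need 0 < r0 <= rs")

    def ranges_for(self, n_features: int) -> tuple[float, float]:
        default = 0.5 * float(np.sqrt(n_features))
        rs = self.rs if self.rs is not None else default
        r0 = self.r0 if self.r0 is not None else rs
        return r0, rs


@dataclass
class Glowworm:
    position: np.ndarray
    luciferin: float = 5.0
    range_: float = 1.0
    fitness: float | None = None
    mask: SelectionMask = field(default=None)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mask is None:
            self.mask = binarize_position(self.position)


def luciferin_update(worm: Glowworm, fitness_value: float, rho: float, gamma: float) -> Glowworm:
    """l ← (1 − ρ)·l + γ·J; fixed point l* = γ·J/ρ for constant J."""
    worm.luciferin = (1.0 - rho) * worm.luciferin + gamma * float(fitness_value)
    worm.fitness = float(fitness_value)
    return worm


def neighbor_probabilities(swarm: list[Glowworm], i: int, range_i: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strictly brighter worms within range, and their move probabilities."""
    xi, li = swarm[i].position, swarm[i].luciferin
    idx = []
    excess = []
    for j, other in enumerate(swarm):
        if j == i:
            continue
        if other.luciferin > li and np.linalg.norm(other.position - xi) < range_i:
            idx.append(j)
            excess.append(other.luciferin - li)
    idx = np.array(idx, dtype=int)
    excess = np.array(excess, dtype=float)
    if idx.size == 0:
        return idx, excess
    return idx, excess / excess.sum()


def glowworm_step(swarm: list[Glowworm], config: GSOConfig, rng=None) -> list[Glowworm]:
    """Synchronous movement + range update for every worm.

    Decisions are made against a snapshot of the swarm, so the update order
    does not matter.  A worm with no brighter neighbour keeps its position but
    still adapts its range toward the desired neighbour count.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    _, rs = config.ranges_for(swarm[0].position.shape[0])
    out = []
    for i, worm in enumerate(swarm):
        neighbors, probs = neighbor_probabilities(swarm, i, worm.range_)
        new_pos = worm.position
        if neighbors.size:
            j = int(rng.choice(neighbors, p=probs))
            direction = swarm[j].position - worm.position
            norm = np.linalg.norm(direction)
            if norm > 0:  # identical positions: direction undefined, skip move
                new_pos = np.clip(worm.position + config.s * direction / norm, 0.0, 1.0)
        new_range = min(rs, max(_RANGE_FLOOR,
                                worm.range_ + config.beta * (config.n_t - neighbors.size)))
        moved = Glowworm(new_pos, luciferin=worm.luciferin, range_=new_range,
                         fitness=worm.fitness)
        out.append(moved)
    return out


class GSOFeatureSelector(BaseWrapperSelector):
    """Glowworm-Swarm feature selector with the sklearn selector API."""

    def __init__(self, n_glowworms: int = 50, max_iterations: int = 100,
                 rho: float = 0.4, gamma: float = 0.6, beta: float = 0.08,
                 n_t: int = 5, s: float = 0.03, l0: float = 5.0,
                 r0: float | None = None, rs: float | None = None, fitness=None,
                 fitness_config: FitnessConfig | None = None, random_state: int = 0):
        super().__init__(fitness=fitness, fitness_config=fitness_config,
                         random_state=random_state)
        self.n_glowworms = n_glowworms
        self.max_iterations = max_iterations
        self.rho = rho
        self.gamma = gamma
        self.beta = beta
        self.n_t = n_t
        self.s = s
        self.l0 = l0
        self.r0 = r0
        self.rs = rs

    def _config(self) -> GSOConfig:
        return GSOConfig(self.n_glowworms, self.max_iterations, self.rho, self.gamma,
                         self.beta, self.n_t, self.s, self.l0, self.r0, self.rs,
                         self.random_state)

    def _optimize(self, n_features, fitness, rng):
        config = self._config()
        r0, _ = config.ranges_for(n_features)
        swarm = [
            Glowworm(rng.random(n_features), luciferin=config.l0, range_=r0)
            for _ in range(config.n_glowworms)
        ]
        trace = []
        for _ in range(config.max_iterations):
            for worm in swarm:
                j = score_of(fitness, binarize_position(worm.position))
                luciferin_update(worm, j, config.rho, config.gamma)
            swarm = glowworm_step(swarm, config, rng)
            trace.append(max(w.luciferin for w in swarm))
        brightest = max(swarm, key=lambda w: w.luciferin)
        mask = binarize_position(brightest.position)
        return mask, score_of(fitness, mask), trace


def run_gso(dataset: ClinicalDataset, config: GSOConfig | None = None,
            fitness=None) -> FitnessResult:
    """Run GSO selection on a preprocessed dataset; return the brightest worm's mask."""
    config = config or GSOConfig()
    selector = GSOFeatureSelector(
        n_glowworms=config.n_glowworms, max_iterations=config.max_iterations,
        rho=config.rho, gamma=config.gamma, beta=config.beta, n_t=config.n_t,
        s=config.s, l0=config.l0, r0=config.r0, rs=config.rs,
        fitness=fitness, random_state=config.seed,
    )
    selector.fit(dataset.X, dataset.y)
    mask = selector.support_mask_.astype(int)
    return FitnessResult(mask, selector.best_fitness_, int(mask.sum()))
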