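"""Correlation-based ensemble feature selection: majority vote, then pruning.

The three wrapper selectors (DE, LOA, GSO) each vote a 0/1 mask; a feature
survives the vote iff at least two of three selectors chose it.  Redundancy
is then removed from the voted set: for every pair of surviving features
whose Pearson correlation magnitude exceeds the threshold (0.95 by default),
the member with the lower information-gain rank is dropped, so the final set
contains no highly correlated pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .data import ClinicalDataset, SelectionMask
from .de import DEFeatureSelector
from .fitness import AdaBoostSVMFitness, FitnessConfig
from .gso import GSOFeatureSelector
from .loa import LOAFeatureSelector
from .preprocess import information_gain_values

__all__ = [
    "ConstantFeatureError",
    "EnsembleResult",
    "majority_vote",
    "pearson_correlation",
    "prune_correlated",
    "run_ensemble",
    "EnsembleFeatureSelector",
]


class ConstantFeatureError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass
class EnsembleResult:
    votes: dict  # selector name -> SelectionMask
    majority: SelectionMask
    pruned_pairs: list  # (kept index, removed index, r)
    final: SelectionMask
    feature_names: list[str] | None = None
    fitnesses: dict = field(default_factory=dict)


def majority_vote(masks) -> SelectionMask:
    """Per-feature mode of exactly three 0/1 masks (selected iff >= 2 votes)."""
    masks = [np.asarray(m, dtype=int) for m in masks]
    if len(masks) != 3:
        raise ValueError("majority vote expects exactly three masks")
    lengths = {m.shape[0] for m in masks}
    if len(lengths) != 1:
        raise ValueError("masks must have equal length")
    return (np.sum(masks, axis=0) >= 2).astype(int)


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation from the raw-sums closed form.

    r = (N·Σxy − Σx·Σy) / sqrt((N·Σx² − (Σx)²)(N·Σy² − (Σy)²))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with N >= 2")
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    dx = n * (x * x).sum() - sx * sx
    dy = n * (y * y).sum() - sy * sy
    if dx <= 0 or dy <= 0:
        raise ConstantFeatureError("correlation undefined for a constant vector")
    return float(num / np.sqrt(dx * dy))


def prune_correlated(
    X: np.ndarray,
    mask: SelectionMask,
    threshold: float = 0.95,
    gains: np.ndarray | None = None,
    y: np.ndarray | None = None,
    use_absolute: bool = True,
) -> tuple[SelectionMask, list[tuple[int, int, float]]]:
    """Drop one member of every selected pair with |r| above the threshold.

    Pairs are scanned in feature-index order; when both members are still
    selected and correlate beyond the threshold, the member with the smaller
    information gain is removed (ties remove the higher index).  Constant
    features correlate with nothing (r treated as 0).
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=int)
    if gains is None:
        if y is None:
            raise ValueError("provide gains or y to rank features for pruning")
        gains = information_gain_values(X, np.asarray(y, dtype=int))
    selected = list(np.where(mask == 1)[0])
    if not selected:
        raise ValueError("mask selects no features")
    keep = set(selected)
    pruned_pairs: list[tuple[int, int, float]] = []
    for ai in range(len(selected)):
        for bi in range(ai + 1, len(selected)):
            a, b = selected[ai], selected[bi]
            if a not in keep or b not in keep:
                continue
            try:
                r = pearson_correlation(X[:, a], X[:, b])
            except ConstantFeatureError:
                r = 0.0
            strength = abs(r) if use_absolute else r
            if strength > threshold:
                # drop the less informative member; ties drop the higher index
                drop, kept = (a, b) if (gains[a], -a) < (gains[b], -b) else (b, a)
                keep.discard(drop)
                pruned_pairs.append((int(kept), int(drop), float(r)))
    final = np.zeros_like(mask)
    final[sorted(keep)] = 1
    return final, pruned_pairs


class EnsembleFeatureSelector(SelectorMixin, BaseEstimator):
    """Vote-then-prune ensemble of the DE, LOA and GSO wrapper selectors.

    All three selectors share one cached fitness evaluator, so a mask visited
    by two algorithms is scored once.  ``de_params`` / ``loa_params`` /
    ``gso_params`` override the individual selector settings (dict of keyword
    arguments); ``fitness`` injects a custom objective for all three.
    """

    def __init__(self, threshold: float = 0.95, de_params: dict | None = None,
                 loa_params: dict | None = None, gso_params: dict | None = None,
                 fitness=None, fitness_config: FitnessConfig | None = None,
                 use_absolute: bool = True, random_state: int = 0):
        self.threshold = threshold
        self.de_params = de_params
        self.loa_params = loa_params
        self.gso_params = gso_params
        self.fitness = fitness
        self.fitness_config = fitness_config
        self.use_absolute = use_absolute
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.fitness is None:
            X, y = check_X_y(X, y)
        else:
            X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        evaluator = self.fitness
        if evaluator is None:
            cfg = self.fitness_config or FitnessConfig(seed=self.random_state)
            evaluator = AdaBoostSVMFitness(X, y, cfg)
        seeds = derive_seeds(self.random_state, 3)
        selectors = {
            "de": DEFeatureSelector(fitness=evaluator, random_state=seeds[0],
                                    **(self.de_params or {})),
            "loa": LOAFeatureSelector(fitness=evaluator, random_state=seeds[1],
                                      **(self.loa_params or {})),
            "gso": GSOFeatureSelector(fitness=evaluator, random_state=seeds[2],
                                      **(self.gso_params or {})),
        }
        votes = {}
        fitnesses = {}
        for name, sel in selectors.items():
            sel.fit(X, y)
            votes[name] = sel.support_mask_.astype(int)
            fitnesses[name] = sel.best_fitness_
        majority = majority_vote([votes["de"], votes["loa"], votes["gso"]])
        if majority.sum() == 0:
            final, pairs = majority.copy(), []
        else:
            gains = (np.zeros(X.shape[1]) if y is None
                     else information_gain_values(X, np.asarray(y, dtype=int)))
            final, pairs = prune_correlated(
                X, majority, self.threshold, gains=gains, use_absolute=self.use_absolute
            )
        self.votes_ = votes
        self.fitnesses_ = fitnesses
        self.majority_ = majority
        self.pruned_pairs_ = pairs
        self.support_mask_ = final.astype(bool)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive n independent 31-bit stage seeds from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_ensemble(
    dataset: ClinicalDataset,
    de_params: dict | None = None,
    loa_params: dict | None = None,
    gso_params: dict | None = None,
    fitness=None,
    fitness_config: FitnessConfig | None = None,
    threshold: float = 0.95,
    seed: int = 0,
) -> EnsembleResult:
    """Run the full ensemble selection on a preprocessed dataset."""
    selector = EnsembleFeatureSelector(
        threshold=threshold, de_params=de_params, loa_params=loa_params,
        gso_params=gso_params, fitness=fitness, fitness_config=fitness_config,
        random_state=seed,
    )
    selector.fit(dataset.X, dataset.y)
    return EnsembleResult(
        votes=selector.votes_,
        majority=selector.majority_,
        pruned_pairs=selector.pruned_pairs_,
        final=selector.support_mask_.astype(int),
        feature_names=dataset.feature_names,
        fitnesses=selector.fitnesses_,
    )
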