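"""Shared machinery for the wrapper feature-selection estimators."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .fitness import AdaBoostSVMFitness, FitnessConfig, as_score


class BaseWrapperSelector(SelectorMixin, BaseEstimator):
    """Wrapper selector: optimize a 0/1 feature mask by classifier accuracy.

    Subclasses implement ``_optimize(n_features, fitness, rng)`` returning
    ``(best_mask, best_fitness, trace)``.  ``fitness`` maps a mask to a score;
    by default it is the boosted-SVM cross-validated accuracy built from the
    training data, but any callable (e.g. a cheap surrogate) can be injected
    via the ``fitness`` parameter for testing or custom objectives.
    """

    def __init__(self, fitness=None, fitness_config: FitnessConfig | None = None,
                 random_state: int = 0):
        self.fitness = fitness
        self.fitness_config = fitness_config
        self.random_state = random_state

    def _build_fitness(self, X, y):
        if self.fitness is not None:
            return self.fitness
        cfg = self.fitness_config or FitnessConfig(seed=self.random_state)
        return AdaBoostSVMFitness(X, y, cfg)

    def fit(self, X, y=None):
        if self.fitness is None:
            X, y = check_X_y(X, y)
        else:
            X = np.asarray(X, dtype=float)
        if X.shape[1] == 0:
            raise ValueError("dataset has no feature columns")
        self.n_features_in_ = X.shape[1]
        evaluator = self._build_fitness(X, y)
        rng = np.random.default_rng(self.random_state)
        mask, best, trace = self._optimize(X.shape[1], evaluator, rng)
        self.support_mask_ = np.asarray(mask, dtype=bool)
        self.best_fitness_ = float(best)
        self.trace_ = list(trace)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def _optimize(self, n_features, fitness, rng):  # pragma: no cover - abstract
        raise NotImplementedError


def score_of(fitness, mask) -> float:
    """Evaluate a mask and coerce the result to a float score."""
    return as_score(fitness(np.asarray(mask, dtype=int)))
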