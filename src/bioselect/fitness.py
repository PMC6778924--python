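"""Wrapper fitness: accuracy of a boosted-SVM ensemble on the masked features.

Each candidate feature subset is scored by the cross-validated accuracy of a
discrete AdaBoost ensemble whose base learner is an RBF support vector
machine.  Results are cached by mask bits, so the metaheuristic selectors can
revisit a subset for free and always see the identical score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .data import ClinicalDataset, SelectionMask

__all__ = [
    "FitnessConfig",
    "FitnessResult",
    "ProtocolError",
    "binarize_position",
    "AdaBoostSVMFitness",
    "evaluate_mask",
]


class ProtocolError(ValueError):
    """The evaluation protocol cannot be applied (e.g. single-class split)."""


class _WeightScaledSVC(SVC):
    """SVC whose sample weights are rescaled to mean 1 before fitting.

    Boosting only uses relative sample weights, but the SVM hinge loss is not
    scale-invariant: weights normalized to sum 1 shrink the effective
    per-sample C by a factor n and collapse the base learner.  Rescaling to
    mean 1 keeps C's usual meaning in every boosting round.
    """

    def fit(self, X, y, sample_weight=None):
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            total = sample_weight.sum()
            if total > 0:
                sample_weight = sample_weight * (len(sample_weight) / total)
        return super().fit(X, y, sample_weight=sample_weight)


@dataclass(frozen=True)
class FitnessConfig:
    """Settings of the boosted-SVM fitness function.

    ``eval_protocol`` is ``"kfold"`` (stratified internal cross-validation,
    ``k`` folds) or ``"holdout"`` (a single stratified split with
    ``holdout_fraction`` held out).
    """

    n_boost_rounds: int = 10
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    eval_protocol: str = "kfold"
    k: int = 3
    holdout_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_boost_rounds < 1:
            raise ValueError("need at least one boosting round")
        if self.eval_protocol == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.eval_protocol == "holdout" and not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be linear or rbf")


@dataclass(frozen=True)
class FitnessResult:
    mask: SelectionMask
    accuracy: float
    n_selected: int


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> SelectionMask:
    """Continuous position in [0,1]^n -> 0/1 mask (bit = 1 iff coord >= threshold)."""
    position = np.asarray(position, dtype=float)
    return (position >= threshold).astype(int)


def as_score(value) -> float:
    """Accept either a plain float fitness or a FitnessResult."""
    return float(value.accuracy) if isinstance(value, FitnessResult) else float(value)


class AdaBoostSVMFitness:
    """Callable mask -> FitnessResult, with a per-mask cache.

    The fold assignment is fixed at construction from ``config.seed``, so the
    same mask always sees the same splits and the score is deterministic.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, config: FitnessConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.config = config or FitnessConfig()
        if len(np.unique(self.y)) < 2:
            raise ProtocolError("training data must contain both classes")
        self._cache: dict[bytes, FitnessResult] = {}
        self.n_evaluations = 0
        cfg = self.config
        if cfg.eval_protocol == "kfold":
            splitter = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
            self._splits = list(splitter.split(self.X, self.y))
        else:
            tr, te = train_test_split(
                np.arange(len(self.y)),
                test_size=cfg.holdout_fraction,
                stratify=self.y,
                random_state=cfg.seed,
            )
            self._splits = [(tr, te)]

    def _make_model(self) -> AdaBoostClassifier:
        cfg = self.config
        base = _WeightScaledSVC(kernel=cfg.svm_kernel, C=cfg.svm_C, gamma="scale")
        return AdaBoostClassifier(
            estimator=base, n_estimators=cfg.n_boost_rounds, random_state=cfg.seed
        )

    def __call__(self, mask: SelectionMask) -> FitnessResult:
        mask = np.asarray(mask, dtype=int)
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n_selected = int(mask.sum())
        if n_selected == 0:
            result = FitnessResult(mask, 0.0, 0)
        else:
            cols = mask.astype(bool)
            accs = []
            for tr, te in self._splits:
                if len(np.unique(self.y[tr])) < 2:
                    raise ProtocolError("single-class training partition")
                model = self._make_model()
                model.fit(self.X[np.ix_(tr, cols)], self.y[tr])
                accs.append(float(model.score(self.X[np.ix_(te, cols)], self.y[te])))
            self.n_evaluations += 1
            result = FitnessResult(mask, float(np.mean(accs)), n_selected)
        self._cache[key] = result
        return result


def evaluate_mask(
    dataset: ClinicalDataset, mask: SelectionMask, config: FitnessConfig | None = None
) -> FitnessResult:
    """Score one mask on a preprocessed dataset (convenience wrapper)."""
    return AdaBoostSVMFitness(dataset.X, dataset.y, config)(mask)
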