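"""Confusion-matrix metrics and stratified k-fold cross-validation.

The four reported metrics are the standard clinical ones, with the adverse
outcome (fatal / malignant) as the positive class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Zero-denominator metrics are flagged as undefined (None), never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import ClinicalDataset, SelectionMask
from .preprocess import fit_normalization

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "StratificationError",
    "compute_metrics",
    "stratified_kfold_cv",
    "format_metrics_table",
]


class StratificationError(ValueError):
    """A class has too few members for the requested fold count."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """Metric fractions in [0, 1]; None marks an undefined (0/0) metric."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None

    def percentages(self, ndigits: int = 3) -> dict[str, float | None]:
        return {
            name: (None if value is None else round(100.0 * value, ndigits))
            for name, value in vars(self).items()
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, sensitivity and specificity from the four counts."""
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def stratified_kfold_cv(
    dataset: ClinicalDataset,
    mask: SelectionMask,
    k: int,
    trainer,
    seed: int = 0,
    normalize_within_fold: bool = False,
    new_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[ConfusionMatrix, list[MetricsReport]]:
    """Stratified k-fold CV of a classifier on the masked features.

    ``trainer(X_train, y_train)`` must return a fitted model with ``predict``.
    In fold-safe mode the min-max parameters are refit on each training part;
    the default reuses the globally preprocessed matrix, mirroring a
    single-pass preprocess-then-validate protocol.
    """
    mask = np.asarray(mask, dtype=int)
    cols = mask.astype(bool)
    counts = np.bincount(dataset.y)
    if counts.min() < k:
        raise StratificationError(f"every class needs >= {k} members for {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = None
    per_fold = []
    for tr, te in splitter.split(dataset.X, dataset.y):
        X_tr, X_te = dataset.X[np.ix_(tr, cols)], dataset.X[np.ix_(te, cols)]
        if normalize_within_fold:
            params = fit_normalization(X_tr, *new_range)
            X_tr, X_te = params.apply(X_tr), params.apply(X_te)
        model = trainer(X_tr, dataset.y[tr])
        cm = ConfusionMatrix.from_predictions(dataset.y[te], model.predict(X_te))
        pooled = cm if pooled is None else pooled + cm
        per_fold.append(compute_metrics(cm))
    return pooled, per_fold


def format_metrics_table(reports: dict[str, MetricsReport], ndigits: int = 3) -> str:
    """Plain-text table: one metric per row, one column per named report."""
    names = list(reports)
    lines = ["Measure\t" + "\t".join(f"{n} (%)" for n in names)]
    for metric in ("accuracy", "precision", "sensitivity", "specificity"):
        cells = []
        for n in names:
            value = reports[n].percentages(ndigits)[metric]
            cells.append("undefined" if value is None else f"{value:g}")
        lines.append(metric.capitalize() + "\t" + "\t".join(cells))
    return "\n".join(lines)
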