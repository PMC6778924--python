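"""Missing-value imputation, min-max normalization, and information gain.

Hot-deck imputation fills each missing cell from the single most similar
donor record of the same class that has the cell observed; similarity is a
Euclidean distance over mutually observed columns with numeric columns
temporarily scaled to [0, 1] and categorical columns contributing a 0/1
mismatch.  Min-max normalization is the affine map

    v' = (v - min_A) / (max_A - min_A) * (new_max - new_min) + new_min

fitted per feature, with the fitted parameters reusable on held-out folds.
Information gain ranks features by the reduction in label entropy after
equal-width discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ClinicalDataset

__all__ = [
    "ImputationError",
    "ImputationReport",
    "NormalizationParams",
    "hot_deck_impute",
    "HotDeckImputer",
    "min_max_normalize",
    "MinMaxNormalizer",
    "information_gain",
    "information_gain_ranking",
]


class ImputationError(ValueError):
    """A record cannot be imputed (e.g. every feature missing)."""


@dataclass
class ImputationReport:
    """Log of imputed cells: (row, column index, donor row, value)."""

    entries: list[tuple[int, int, int, float]] = field(default_factory=list)
    cross_class_fallbacks: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _scaled_matrix(X: np.ndarray, categorical: np.ndarray) -> np.ndarray:
    """Min-max scale numeric columns to [0,1] for distance computation only."""
    S = X.copy()
    for j in range(X.shape[1]):
        if categorical[j]:
            continue
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        lo, hi = obs.min(), obs.max()
        if hi > lo:
            S[:, j] = (col - lo) / (hi - lo)
        else:
            S[:, j] = 0.0
    return S


def _donor_distance(S: np.ndarray, categorical: np.ndarray, r: int, d: int) -> float:
    """Distance between rows r and d over mutually observed columns."""
    a, b = S[r], S[d]
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        return np.inf
    diff = np.where(categorical[both], (a[both] != b[both]).astype(float), a[both] - b[both])
    return float(np.sqrt(np.sum(diff**2)))


def _impute_matrix(
    X: np.ndarray,
    y: np.ndarray,
    categorical: np.ndarray,
    same_class_only: bool = True,
) -> tuple[np.ndarray, ImputationReport]:
    report = ImputationReport()
    out = X.copy()
    S = _scaled_matrix(X, categorical)
    missing_rows = np.where(np.isnan(X).any(axis=1))[0]
    for r in missing_rows:
        if np.isnan(X[r]).all():
            raise ImputationError(f"record {r} is missing every feature")
        for c in np.where(np.isnan(X[r]))[0]:
            observed_in_c = ~np.isnan(X[:, c])
            candidates = np.where(observed_in_c & (y == y[r]))[0]
            fallback = False
            if candidates.size == 0 and same_class_only:
                candidates = np.where(observed_in_c)[0]
                fallback = True
            if candidates.size == 0:
                raise ImputationError(f"no donor for cell ({r}, {c})")
            dists = np.array([_donor_distance(S, categorical, r, d) for d in candidates])
            donor = int(candidates[int(np.argmin(dists))])  # argmin ties -> lowest index
            out[r, c] = X[donor, c]
            report.entries.append((int(r), int(c), donor, float(X[donor, c])))
            if fallback:
                report.cross_class_fallbacks.append((int(r), int(c)))
    return out, report


def hot_deck_impute(
    dataset: ClinicalDataset, same_class_only: bool = True
) -> tuple[ClinicalDataset, ImputationReport]:
    """Fill every missing cell from its nearest eligible donor record.

    Donors must have the cell observed and (by default) share the record's
    class; when no same-class donor exists the most similar donor of any class
    is used and logged.  Ties in distance resolve to the lowest row index, so
    the result is deterministic.  Non-missing cells are never altered.
    """
    categorical = np.array([s.kind != "numeric" for s in dataset.feature_specs])
    Xi, report = _impute_matrix(dataset.X, dataset.y, categorical, same_class_only)
    out = dataset.copy()
    out.X = Xi
    return out, report


class HotDeckImputer(TransformerMixin, BaseEstimator):
    """Fold-safe hot-deck imputer: donors come from the fitted training data."""

    def __init__(self, same_class_only: bool = True, categorical_features=None):
        self.same_class_only = same_class_only
        self.categorical_features = categorical_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.donors_X_ = X.copy()
        self.donors_y_ = np.asarray(y, dtype=int)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        categorical = np.zeros(self.n_features_in_, dtype=bool)
        if self.categorical_features is not None:
            categorical[np.asarray(self.categorical_features)] = True
        n_new = X.shape[0]
        # stack query rows under the training donors; only query cells imputed
        stack = np.vstack([self.donors_X_, X])
        S = _scaled_matrix(stack, categorical)
        out = X.copy()
        for i in range(n_new):
            r = self.donors_X_.shape[0] + i
            for c in np.where(np.isnan(X[i]))[0]:
                candidates = np.where(~np.isnan(self.donors_X_[:, c]))[0]
                if candidates.size == 0:
                    raise ImputationError(f"no donor for column {c}")
                dists = np.array(
                    [_donor_distance(S, categorical, r, d) for d in candidates]
                )
                donor = int(candidates[int(np.argmin(dists))])
                out[i, c] = self.donors_X_[donor, c]
        return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Fitted per-feature min/max plus the target range; reusable & invertible."""

    min_: np.ndarray
    max_: np.ndarray
    new_min: float
    new_max: float
    zero_range: np.ndarray  # flagged columns with max == min

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.zero_range, 1.0, self.max_ - self.min_)
        out = (X - self.min_) / span * (self.new_max - self.new_min) + self.new_min
        out[:, self.zero_range] = self.new_min
        return out

    def invert(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.asarray(Xn, dtype=float)
        span = np.where(self.zero_range, 1.0, self.max_ - self.min_)
        return (Xn - self.new_min) / (self.new_max - self.new_min) * span + self.min_


def fit_normalization(X: np.ndarray, new_min: float = 0.0, new_max: float = 1.0) -> NormalizationParams:
    if not new_max > new_min:
        raise ValueError("new_max must exceed new_min")
    if np.isnan(X).any():
        raise ValueError("normalize after imputation: missing values present")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    return NormalizationParams(lo, hi, float(new_min), float(new_max), hi == lo)


def min_max_normalize(
    dataset: ClinicalDataset, new_min: float = 0.0, new_max: float = 1.0
) -> tuple[ClinicalDataset, NormalizationParams]:
    """Scale every feature into [new_min, new_max]; zero-range columns map to new_min."""
    params = fit_normalization(dataset.X, new_min, new_max)
    out = dataset.copy()
    out.X = params.apply(dataset.X)
    return out, params


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper over :func:`fit_normalization`."""

    def __init__(self, new_min: float = 0.0, new_max: float = 1.0):
        self.new_min = new_min
        self.new_max = new_max

    def fit(self, X, y=None):
        self.params_ = fit_normalization(np.asarray(X, dtype=float), self.new_min, self.new_max)
        self.n_features_in_ = self.params_.min_.shape[0]
        return self

    def transform(self, X):
        return self.params_.apply(np.asarray(X, dtype=float))

    def inverse_transform(self, X):
        return self.params_.invert(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# information gain
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros(col.shape, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)


def information_gain(
    col: np.ndarray, y: np.ndarray, n_bins: int = 10, categorical: bool = False
) -> float:
    """H(y) minus the bin-weighted conditional entropy of y given the feature."""
    bins = col.astype(int) if categorical else _discretize(col, n_bins)
    hy = _entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.mean() * _entropy(y[sel])
    return hy - cond


def information_gain_ranking(
    dataset: ClinicalDataset, n_bins: int = 10
) -> list[tuple[str, float]]:
    """Features sorted by descending information gain (rank 1 = largest).

    Numeric features use ``n_bins`` equal-width bins; coded categorical and
    boolean features use their codes as bins directly.
    """
    if np.isnan(dataset.X).any():
        raise ValueError("rank after imputation: missing values present")
    gains = []
    for j, spec in enumerate(dataset.feature_specs):
        g = information_gain(
            dataset.X[:, j], dataset.y, n_bins=n_bins, categorical=spec.kind != "numeric"
        )
        gains.append((spec.name, g))
    # stable sort keeps original column order among exact ties
    return sorted(gains, key=lambda t: -t[1])


def information_gain_values(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Per-column gains for a plain numeric matrix (used by pruning tie-breaks)."""
    return np.array([information_gain(X[:, j], y, n_bins=n_bins) for j in range(X.shape[1])])
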