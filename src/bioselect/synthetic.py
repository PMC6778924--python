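"""Synthetic clinical-style tables with known ground truth.

The generator emulates the statistical structure the selection pipeline
assumes in real clinical tables: class-informative Gaussian features (class
means separated by a chosen standardized effect size), near-duplicate
redundant features (a parent plus small Gaussian noise, pairwise correlation
above 0.95), pure-noise features, a binary label, and optional missing
cells.  Because the class-conditional model is Gaussian, a single informative
feature has the closed-form Bayes accuracy Φ(effect_size / 2), which the
tests use as an analytic anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClinicalDataset, FeatureSpec

__all__ = ["SyntheticSpec", "generate_dataset", "inject_missing"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_instances: int = 300
    n_informative: int = 3
    n_redundant: int = 3
    n_noise: int = 6
    class_balance: float = 0.5
    effect_size: float = 1.5
    noise_sd: float = 0.15
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need an informative parent")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.n_redundant > 0 and self.expected_parent_correlation() <= 0.95:
            raise ValueError(
                "noise_sd too large: expected parent-child correlation "
                f"{self.expected_parent_correlation():.4f} <= 0.95"
            )

    def expected_parent_correlation(self) -> float:
        """Population corr(parent, parent + N(0, noise_sd^2))."""
        p = self.class_balance
        parent_var = 1.0 + (self.effect_size**2) * p * (1 - p)
        return float(np.sqrt(parent_var / (parent_var + self.noise_sd**2)))

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def generate_dataset(spec: SyntheticSpec) -> tuple[ClinicalDataset, dict]:
    """Draw one table; return it with its ground truth.

    Ground truth: ``informative`` (mask over features), ``redundant_map``
    (child column -> parent column), ``noise`` (mask).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    y = (rng.random(n) < spec.class_balance).astype(int)
    if y.min() == y.max():  # force both classes present
        y[0] = 1 - y[0]
    shift = np.where(y == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)

    columns = []
    specs = []
    informative_idx = []
    redundant_map = {}
    noise_idx = []
    for i in range(spec.n_informative):
        columns.append(rng.normal(0.0, 1.0, size=n) + shift)
        specs.append(FeatureSpec(f"informative_{i}"))
        informative_idx.append(len(columns) - 1)
    for i in range(spec.n_redundant):
        parent = informative_idx[i % spec.n_informative]
        columns.append(columns[parent] + rng.normal(0.0, spec.noise_sd, size=n))
        specs.append(FeatureSpec(f"redundant_{i}_of_informative_{parent}"))
        redundant_map[len(columns) - 1] = parent
    for i in range(spec.n_noise):
        columns.append(rng.normal(0.0, 1.0, size=n))
        specs.append(FeatureSpec(f"noise_{i}"))
        noise_idx.append(len(columns) - 1)
    specs.append(FeatureSpec("outcome", kind="categorical", role="class",
                             categories=("control", "case")))
    X = np.column_stack(columns)
    dataset = ClinicalDataset(specs, X, y, positive_label="case",
                              negative_label="control")
    d = spec.n_features
    truth = {
        "informative": np.isin(np.arange(d), informative_idx).astype(int),
        "redundant_map": redundant_map,
        "noise": np.isin(np.arange(d), noise_idx).astype(int),
    }
    if spec.missing_rate > 0:
        dataset = inject_missing(dataset, spec.missing_rate, seed=spec.seed + 1)
    return dataset, truth


def inject_missing(dataset: ClinicalDataset, missing_rate: float, seed: int = 0) -> ClinicalDataset:
    """Blank feature cells independently at the given rate.

    One record per class is protected so hot-deck imputation always has a
    complete same-class donor; the class column is never blanked (labels are
    stored separately from the feature matrix).
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    out = dataset.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    blank = rng.random(out.X.shape) < missing_rate
    for cls in (0, 1):
        rows = np.where(out.y == cls)[0]
        if rows.size == 0:
            raise ValueError("both classes must be present")
        blank[rows[0], :] = False  # protected complete record
    out.X[blank] = np.nan
    for cls in (0, 1):
        rows = np.where(out.y == cls)[0]
        if not (~np.isnan(out.X[rows]).any(axis=1)).any():
            raise RuntimeError("missing rate left a class with no complete record")
    return out
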