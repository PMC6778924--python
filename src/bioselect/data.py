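"""Tabular clinical dataset container and CSV/ARFF readers.

A :class:`ClinicalDataset` is an in-memory numeric matrix of clinical
attributes plus a binary outcome, in the shape UCI-style tables (Hepatitis,
WDBC) ship in: one column per attribute, ``"?"`` marking missing cells, and a
single class column.  Categorical and boolean attributes are mapped to stable
integer codes so that imputation, correlation and classification all operate
on one float matrix; missing cells carry ``NaN`` as the internal sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = [
    "FeatureSpec",
    "ClinicalDataset",
    "SelectionMask",
    "FormatError",
    "SchemaError",
    "UnsupportedLabelError",
    "read_dataset",
    "write_dataset",
    "encode_labels",
    "validate_schema",
]

#: type alias used throughout the package — a 0/1 vector over feature columns
SelectionMask = np.ndarray


class FormatError(ValueError):
    """The input file could not be parsed in the requested format."""


class SchemaError(ValueError):
    """The table violates the expected schema (e.g. no class column)."""


class UnsupportedLabelError(ValueError):
    """The class column is not binary."""


@dataclass(frozen=True)
class FeatureSpec:
    """Description of one column: its name, value kind, and role.

    ``categories`` records, for categorical/boolean columns, the original
    values in the order they were assigned integer codes (first appearance),
    so encoding is reproducible and reversible.
    """

    name: str
    kind: str = "numeric"  # numeric | boolean | categorical
    role: str = "feature"  # feature | identifier | class
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "boolean", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.role not in ("feature", "identifier", "class"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ClinicalDataset:
    """Numeric feature matrix with missing sentinel and a binary label.

    ``specs`` lists every column (features, identifiers and exactly one class
    column); ``X`` holds the non-class columns in spec order with ``NaN`` for
    missing cells; ``y`` is the 0/1-encoded class with ``positive_label``
    mapped to 1.
    """

    specs: list[FeatureSpec]
    X: np.ndarray
    y: np.ndarray
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        class_specs = [s for s in self.specs if s.role == "class"]
        if len(class_specs) != 1:
            raise SchemaError("exactly one class column required")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("column names must be unique")
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise SchemaError("X and y row counts differ")
        if self.X.shape[0] < 2:
            raise SchemaError("need at least 2 instances")
        if self.X.shape[1] != len(self.feature_specs):
            raise SchemaError("X column count does not match specs")

    # -- convenience views -------------------------------------------------
    @property
    def feature_specs(self) -> list[FeatureSpec]:
        return [s for s in self.specs if s.role != "class"]

    @property
    def class_spec(self) -> FeatureSpec:
        return next(s for s in self.specs if s.role == "class")

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.X)

    def n_missing(self) -> int:
        return int(self.missing_mask().sum())

    def labels(self) -> np.ndarray:
        """Original label strings, row by row."""
        lut = np.array([self.negative_label, self.positive_label], dtype=object)
        return lut[self.y]

    def copy(self) -> "ClinicalDataset":
        return ClinicalDataset(
            specs=list(self.specs),
            X=self.X.copy(),
            y=self.y.copy(),
            positive_label=self.positive_label,
            negative_label=self.negative_label,
        )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _encode_column(values: pd.Series, spec: FeatureSpec | None, name: str) -> tuple[np.ndarray, FeatureSpec]:
    """Map one raw column to floats; non-numeric values get stable codes."""
    raw = values.to_numpy(dtype=object)
    observed = [v for v in raw if v is not None]
    numeric = np.full(len(raw), np.nan)
    if spec is not None and spec.categories is not None:
        codes = {c: i for i, c in enumerate(spec.categories)}
        for i, v in enumerate(raw):
            if v is None:
                continue
            if v not in codes:
                raise SchemaError(f"value {v!r} not in declared categories of {name!r}")
            numeric[i] = codes[v]
        return numeric, spec
    # try numeric
    try:
        for i, v in enumerate(raw):
            if v is not None:
                numeric[i] = float(v)
        kind = spec.kind if spec is not None else "numeric"
        role = spec.role if spec is not None else "feature"
        return numeric, FeatureSpec(name, kind=kind, role=role)
    except (TypeError, ValueError):
        pass
    # categorical: integer codes in first-appearance order
    categories: list = []
    codes = {}
    for v in observed:
        if v not in codes:
            codes[v] = len(categories)
            categories.append(v)
    for i, v in enumerate(raw):
        if v is not None:
            numeric[i] = codes[v]
    kind = "boolean" if len(categories) <= 2 else "categorical"
    if spec is not None:
        kind, role = spec.kind, spec.role
    else:
        role = "feature"
    return numeric, FeatureSpec(name, kind=kind, role=role, categories=tuple(categories))


def _finish_dataset(
    frame: pd.DataFrame,
    class_column: str | int | None,
    schema: Sequence[FeatureSpec] | None,
    positive_label: str | None,
) -> ClinicalDataset:
    columns = list(frame.columns)
    if class_column is None:
        class_name = columns[-1]
    elif isinstance(class_column, int):
        class_name = columns[class_column]
    else:
        if class_column not in columns:
            raise SchemaError(f"class column {class_column!r} absent")
        class_name = class_column
    schema_by_name = {s.name: s for s in schema} if schema else {}

    specs: list[FeatureSpec] = []
    feature_cols: list[np.ndarray] = []
    for name in columns:
        if name == class_name:
            continue
        col, spec = _encode_column(frame[name], schema_by_name.get(name), name)
        specs.append(spec)
        feature_cols.append(col)

    labels = frame[class_name].to_numpy(dtype=object)
    if any(v is None for v in labels):
        raise UnsupportedLabelError("missing values in the class column")
    labels = np.array([str(v) for v in labels], dtype=object)
    uniques = list(dict.fromkeys(labels))
    if len(uniques) != 2:
        raise UnsupportedLabelError(
            f"class column must be binary, found {len(uniques)} labels: {uniques}"
        )
    if positive_label is None:
        positive_label = uniques[1]
    elif positive_label not in uniques:
        raise UnsupportedLabelError(f"positive label {positive_label!r} not found")
    negative_label = next(u for u in uniques if u != positive_label)
    y = (labels == positive_label).astype(int)

    class_spec = schema_by_name.get(class_name) or FeatureSpec(
        class_name, kind="categorical", role="class", categories=tuple(uniques)
    )
    if class_spec.role != "class":
        class_spec = replace(class_spec, role="class")
    specs.append(class_spec)

    X = np.column_stack(feature_cols) if feature_cols else np.empty((len(y), 0))
    return ClinicalDataset(specs, X, y, positive_label, negative_label)


def read_dataset(
    path,
    format: str | None = None,
    missing_marker: str = "?",
    class_column: str | int | None = None,
    header: bool = True,
    schema: Sequence[FeatureSpec] | None = None,
    positive_label: str | None = None,
) -> ClinicalDataset:
    """Read a CSV or ARFF clinical table into a :class:`ClinicalDataset`.

    The class column is identified by name or position (default: last).
    Cells equal to ``missing_marker`` become the internal ``NaN`` sentinel.
    ``schema`` optionally fixes column kinds/roles and categorical code order,
    which makes read→write→read round-trips exact.
    """
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    if format == "csv":
        try:
            frame = pd.read_csv(
                path,
                header=0 if header else None,
                dtype=object,
                na_values=[missing_marker],
                keep_default_na=False,
                skipinitialspace=True,
            )
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
        if not header:
            frame.columns = [f"f{i}" for i in range(frame.shape[1])]
    elif format == "arff":
        try:
            data, meta = scipy_arff.loadarff(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as ARFF: {exc}") from exc
        frame = pd.DataFrame(data)
        for name in frame.columns:
            if frame[name].dtype == object:
                frame[name] = frame[name].map(
                    lambda b: b.decode() if isinstance(b, bytes) else b
                )
                frame.loc[frame[name] == missing_marker, name] = np.nan
    else:
        raise FormatError(f"unknown format {format!r}")
    frame = frame.where(pd.notna(frame), None)
    return _finish_dataset(frame, class_column, schema, positive_label)


def write_dataset(dataset: ClinicalDataset, path, missing_marker: str = "?") -> None:
    """Write the dataset back to CSV with original category/label values."""
    rows = []
    for i in range(dataset.n_instances):
        row = []
        for j, spec in enumerate(dataset.feature_specs):
            v = dataset.X[i, j]
            if np.isnan(v):
                row.append(missing_marker)
            elif spec.categories is not None:
                row.append(str(spec.categories[int(v)]))
            else:
                row.append(repr(float(v)))
        row.append(dataset.labels()[i])
        rows.append(row)
    header = dataset.feature_names + [dataset.class_spec.name]
    frame = pd.DataFrame(rows, columns=header)
    frame.to_csv(path, index=False)


def encode_labels(dataset: ClinicalDataset, positive_label: str) -> ClinicalDataset:
    """Re-encode the binary label so that ``positive_label`` maps to 1.

    Idempotent: applying twice with the same positive label is a no-op.
    """
    if positive_label == dataset.positive_label:
        return dataset.copy()
    if positive_label != dataset.negative_label:
        raise ValueError(
            f"positive label {positive_label!r} not among "
            f"({dataset.negative_label!r}, {dataset.positive_label!r})"
        )
    out = dataset.copy()
    out.y = 1 - out.y
    out.positive_label = dataset.negative_label
    out.negative_label = dataset.positive_label
    return out


def validate_schema(dataset: ClinicalDataset) -> dict:
    """Report per-column missing counts, observed ranges, and constant columns."""
    columns = {}
    for j, spec in enumerate(dataset.feature_specs):
        col = dataset.X[:, j]
        observed = col[~np.isnan(col)]
        columns[spec.name] = {
            "missing": int(np.isnan(col).sum()),
            "min": float(observed.min()) if observed.size else None,
            "max": float(observed.max()) if observed.size else None,
            "constant": bool(observed.size and np.all(observed == observed[0])),
            "kind": spec.kind,
            "role": spec.role,
        }
    return {
        "n_instances": dataset.n_instances,
        "n_features": dataset.n_features,
        "total_missing": dataset.n_missing(),
        "class_balance": float(dataset.y.mean()),
        "columns": columns,
    }
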