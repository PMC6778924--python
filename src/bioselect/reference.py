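"""Reference tables for the UCI Hepatitis and WDBC selection experiments.

These are the published per-feature vote masks of the three wrapper
selectors, the published final ensemble masks, and the published confusion
matrices of the backpropagation classifier on the two UCI datasets.  They are
shipped as small plain-data constants so the ensemble vote rule and the
metric formulas can be exercised and demonstrated without downloading the
datasets themselves.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HEPATITIS_ATTRIBUTES",
    "HEPATITIS_VOTES",
    "HEPATITIS_ENSEMBLE",
    "WDBC_ATTRIBUTES",
    "WDBC_VOTES",
    "WDBC_ENSEMBLE",
    "HEPATITIS_CONFUSION",
    "WDBC_CONFUSION",
]

# 18 non-class attributes of the UCI Hepatitis table
HEPATITIS_ATTRIBUTES = (
    "Age", "Sex", "Steroid", "Antivirals", "Fatigue", "Malaise", "Anorexia",
    "Liver_big", "Liver_firm", "Spleen_palpable", "Spiders", "Ascites",
    "Varices", "Bilirubin", "Alk_phosphate", "Sgot", "Albumin", "Histology",
)

HEPATITIS_VOTES = {
    "de":   np.array([1, 0, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 0, 0]),
    "gso":  np.array([1, 1, 0, 1, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1]),
    "lion": np.array([1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]),
}

# published final mask of the correlation-based ensemble selector
HEPATITIS_ENSEMBLE = np.array([1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1])

# 31 non-class attributes of the UCI WDBC table (identifier included)
WDBC_ATTRIBUTES = (
    "P_id", "Mean_radius", "Mean_texture", "Mean_perimeter", "Mean_area",
    "Mean_smoothness", "Mean_compactness", "Mean_concavity",
    "Concavepoints_mean", "Mean_symmetry", "Mean_fractaldimension",
    "Standard_error_radius", "Standard_error_texture",
    "Standard_error_perimeter", "Standard_error_area",
    "Standard_error_smoothness", "Standard_error_compactness",
    "Standard_error_concavity", "Concavepoints_standard_error",
    "Standard_error_symmetry", "Standard_error_fractaldimension",
    "Worst_radius", "Worst_texture", "Worst_perimeter", "Worst_area",
    "Worst_smoothness", "Worst_compactness", "Worst_concavity",
    "Concavepoints_worst", "Worst_symmetry", "Worst_fractaldimension",
)

WDBC_VOTES = {
    "de":   np.array([0, 0, 1, 0, 1, 0, 0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 0, 1,
                      0, 1, 1, 0, 1, 1, 1, 1, 1, 1, 0, 1]),
    "gso":  np.array([0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 0, 1, 0, 0,
                      0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1]),
    "lion": np.array([0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 0,
                      1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0]),
}

WDBC_ENSEMBLE = np.array([0, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 1, 0,
                          0, 0, 0, 0, 1, 0, 0, 1, 1, 1, 1, 1, 1])

# published confusion matrices of the classifier on the two datasets
# keys: tn, fp, fn, tp (positive class = fatal / malignant)
HEPATITIS_CONFUSION = {"tn": 38, "fp": 2, "fn": 3, "tp": 39}
WDBC_CONFUSION = {"tn": 118, "fp": 2, "fn": 1, "tp": 116}
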