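"""Reference calibration of the two-form 49-item field administration.

The generator's eleven fielded item models (3-13) were calibrated in a
two-form online administration (Form A: models 3, 4, 6, 8, 10, 12; Form B:
models 3, 5, 7, 8, 9, 11, 13; model-3 and model-8 items anchoring the two
forms).  This module ships the resulting published estimates: per-item Rasch
difficulties with standard errors, the operator easiness coefficients of the
LLTM and LLTM-plus-error fits, and the external-validity summary statistics.
They serve as realistic inputs for form assembly, test-information studies
and respondent simulation, and as fixed coefficient sets for difficulty
prediction of newly generated items.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_items",
    "reference_difficulties",
    "form_item_ids",
    "LLTM_COEFFICIENTS",
    "LLTM_ERROR_COEFFICIENTS",
    "PERSON_SEPARATION",
    "EXTERNAL_TEST",
]

# item id, item model, Rasch estimate, Rasch SE, LLTM prediction,
# LLTM bootstrap SE, LLTM+error prediction, LLTM+error bootstrap SE
_ITEM_ROWS = [
    (1, 3, -2.62, 0.18, -2.46, 0.07, -2.60, 0.34),
    (2, 3, -2.86, 0.19, -2.46, 0.07, -2.60, 0.34),
    (3, 3, -2.39, 0.16, -2.46, 0.07, -2.60, 0.34),
    (4, 3, -2.20, 0.16, -2.46, 0.07, -2.60, 0.34),
    (5, 3, -2.06, 0.15, -2.46, 0.07, -2.60, 0.34),
    (6, 4, -3.10, 0.24, -3.24, 0.14, -3.49, 0.58),
    (7, 4, -2.72, 0.21, -3.24, 0.14, -3.49, 0.58),
    (8, 4, -3.80, 0.31, -3.24, 0.14, -3.49, 0.58),
    (9, 5, -0.91, 0.21, -0.59, 0.07, -0.40, 0.36),
    (10, 5, -0.57, 0.20, -0.59, 0.07, -0.40, 0.36),
    (11, 5, -0.19, 0.19, -0.59, 0.07, -0.40, 0.36),
    (12, 5, 3.80, 0.32, -0.59, 0.07, -0.40, 0.36),
    (13, 5, -0.61, 0.20, -0.59, 0.07, -0.40, 0.36),
    (14, 6, -0.97, 0.14, -1.36, 0.06, -1.40, 0.31),
    (15, 6, -1.83, 0.17, -1.36, 0.06, -1.40, 0.31),
    (16, 6, 0.16, 0.13, -1.36, 0.06, -1.40, 0.31),
    (17, 6, -1.73, 0.16, -1.36, 0.06, -1.40, 0.31),
    (18, 7, -0.76, 0.21, -1.36, 0.06, -1.40, 0.31),
    (19, 7, -0.19, 0.19, -1.36, 0.06, -1.40, 0.31),
    (20, 7, 0.39, 0.19, -1.36, 0.06, -1.40, 0.31),
    (21, 7, 0.36, 0.19, -1.36, 0.06, -1.40, 0.31),
    (22, 7, -1.26, 0.22, -1.36, 0.06, -1.40, 0.31),
    (23, 8, 0.67, 0.11, 0.01, 0.06, 0.01, 0.50),
    (24, 8, 0.18, 0.11, 0.01, 0.06, 0.01, 0.50),
    (25, 8, 0.19, 0.11, 0.01, 0.06, 0.01, 0.50),
    (26, 8, 0.85, 0.11, 0.01, 0.06, 0.01, 0.50),
    (27, 9, -1.08, 0.22, -0.33, 0.07, -0.35, 0.27),
    (28, 9, -1.50, 0.24, -0.33, 0.07, -0.35, 0.27),
    (29, 9, -0.87, 0.21, -0.33, 0.07, -0.35, 0.27),
    (30, 9, -0.87, 0.21, -0.33, 0.07, -0.35, 0.27),
    (31, 9, -0.50, 0.20, -0.33, 0.07, -0.35, 0.27),
    (32, 10, 1.97, 0.15, 0.51, 0.06, 0.80, 0.32),
    (33, 10, -0.42, 0.13, 0.51, 0.06, 0.80, 0.32),
    (34, 10, -0.86, 0.14, 0.51, 0.06, 0.80, 0.32),
    (35, 10, 1.55, 0.14, 0.51, 0.06, 0.80, 0.32),
    (36, 10, 1.09, 0.13, 0.51, 0.06, 0.80, 0.32),
    (37, 11, 1.62, 0.20, -0.33, 0.07, -0.35, 0.27),
    (38, 11, 0.11, 0.19, -0.33, 0.07, -0.35, 0.27),
    (39, 11, 0.51, 0.19, -0.33, 0.07, -0.35, 0.27),
    (40, 11, 0.39, 0.19, -0.33, 0.07, -0.35, 0.27),
    (41, 11, 1.29, 0.19, -0.33, 0.07, -0.35, 0.27),
    (42, 12, 2.98, 0.18, 1.54, 0.07, 1.84, 0.29),
    (43, 12, 4.01, 0.25, 1.54, 0.07, 1.84, 0.29),
    (44, 12, 1.76, 0.14, 1.54, 0.07, 1.84, 0.29),
    (45, 13, 1.10, 0.19, 1.54, 0.07, 1.84, 0.29),
    (46, 13, 3.80, 0.32, 1.54, 0.07, 1.84, 0.29),
    (47, 13, 3.91, 0.33, 1.54, 0.07, 1.84, 0.29),
    (48, 13, 1.13, 0.19, 1.54, 0.07, 1.84, 0.29),
    (49, 13, 3.08, 0.26, 1.54, 0.07, 1.84, 0.29),
]

#: Published operator easiness coefficients (fixed effects) and variance
#: components of the two explanatory fits.
LLTM_COEFFICIENTS = {
    "intercept": 4.77,
    "eta": {"AOS": 0.35, "PS": -1.53, "CF": -2.13, "NPCP": -2.65, "PCP": -3.76},
    "person_var": 1.19,
}
LLTM_ERROR_COEFFICIENTS = {
    "intercept": 5.32,
    "eta": {"AOS": 0.37, "PS": -1.83, "CF": -2.25, "NPCP": -3.09, "PCP": -4.28},
    "person_var": 1.67,
    "item_resid_var": 1.03,
}

#: Person-separation reliability of the calibrated forms.
PERSON_SEPARATION = {"A": 0.85, "B": 0.89}

#: External cognitive-ability short-form test: internal consistency and raw
#: correlations of its total score with number-series ability per form.
EXTERNAL_TEST = {"alpha": 0.68, "r_form": {"A": 0.60, "B": 0.66}}

#: Item-model composition of the calibrated forms (49 items after misfit removal).
_FORM_MODELS = {"A": (3, 4, 6, 8, 10, 12), "B": (3, 5, 7, 8, 9, 11, 13)}


def reference_items() -> pd.DataFrame:
    """Published per-item estimates, indexed by item id."""
    df = pd.DataFrame(
        _ITEM_ROWS,
        columns=["item", "item_model", "rasch", "rasch_se",
                 "lltm", "lltm_boot_se", "lltm_error", "lltm_error_boot_se"],
    ).set_index("item")
    return df


def reference_difficulties(form: str | None = None, column: str = "rasch") -> pd.Series:
    """Difficulty estimates, optionally restricted to one form's item models."""
    df = reference_items()
    if form is not None:
        df = df[df.item_model.isin(_FORM_MODELS[form.upper()])]
    return df[column]


def form_item_ids(form: str) -> list[int]:
    """Item ids belonging to a calibrated form."""
    df = reference_items()
    return list(df.index[df.item_model.isin(_FORM_MODELS[form.upper()])])
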