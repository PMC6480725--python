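"""Cognitive-operator design matrices (Q-matrices) for the item models.

Two published schemes are built in: the five-operator scheme underlying the
generator (apprehension of succession AOS, parallel sequences PS, cluster
formation CF, non-progressive NPCP and progressive PCP coefficient patterns)
and the four-determinant scheme of Holzman, Pellegrino and Glaser (relation
detection RD, discovery of periodicity DoP, pattern description PD,
extrapolation Ex).  The Holzman scheme is nested in the five-operator one:
RD = CF, DoP = PS, PD = Ex = NPCP + 2*PCP, so every Holzman column lies in
the five-operator column span.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANSIG_OPERATORS",
    "ANSIG_WEIGHTS",
    "HOLZMAN_OPERATORS",
    "HOLZMAN_WEIGHTS",
    "QMatrix",
    "ItemPropertyMatrix",
    "build_qmatrix",
    "expand_item_properties",
    "distinct_profiles",
    "check_nesting",
]

ANSIG_OPERATORS = ("AOS", "PS", "CF", "NPCP", "PCP")
ANSIG_WEIGHTS = (
    (1, 0, 0, 0, 0),   # 1
    (0, 0, 1, 0, 0),   # 2
    (1, 0, 0, 1, 0),   # 3
    (0, 1, 0, 0, 0),   # 4
    (0, 1, 0, 1, 0),   # 5
    (1, 0, 0, 0, 1),   # 6
    (1, 0, 0, 0, 1),   # 7
    (0, 0, 1, 1, 0),   # 8
    (1, 0, 1, 1, 0),   # 9
    (0, 1, 0, 0, 1),   # 10
    (1, 0, 1, 1, 0),   # 11
    (0, 1, 1, 1, 0),   # 12
    (0, 1, 1, 1, 0),   # 13
)

HOLZMAN_OPERATORS = ("RD", "DoP", "PD", "Ex")
HOLZMAN_WEIGHTS = (
    (0, 0, 0, 0),   # 1
    (1, 0, 0, 0),   # 2
    (0, 0, 1, 1),   # 3
    (0, 1, 0, 0),   # 4
    (0, 1, 1, 1),   # 5
    (0, 0, 2, 2),   # 6
    (0, 0, 2, 2),   # 7
    (1, 0, 1, 1),   # 8
    (1, 0, 1, 1),   # 9
    (0, 1, 2, 2),   # 10
    (1, 0, 1, 1),   # 11
    (1, 1, 1, 1),   # 12
    (1, 1, 1, 1),   # 13
)

_SCHEMES = {
    "ansig": (ANSIG_OPERATORS, ANSIG_WEIGHTS),
    "holzman": (HOLZMAN_OPERATORS, HOLZMAN_WEIGHTS),
}


@dataclasses.dataclass(frozen=True)
class QMatrix:
    """Item-model x cognitive-operator weight matrix."""

    scheme: str
    model_ids: tuple[int, ...]
    operator_names: tuple[str, ...]
    weights: np.ndarray  # shape (n_models, n_operators), non-negative ints

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=int)
        if w.ndim != 2 or w.shape != (len(self.model_ids), len(self.operator_names)):
            raise ValueError("weight matrix shape does not match labels")
        if (w < 0).any():
            raise ValueError("Q-matrix entries must be non-negative")
        object.__setattr__(self, "weights", w)

    def row(self, model_id: int) -> tuple[int, ...]:
        idx = self.model_ids.index(int(model_id))
        return tuple(int(x) for x in self.weights[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=pd.Index(self.model_ids, name="model_id"),
                            columns=list(self.operator_names))


@dataclasses.dataclass(frozen=True)
class ItemPropertyMatrix:
    """Per-item operator weights: each item inherits its model's Q-row."""

    item_ids: tuple[str, ...]
    model_ids: tuple[int, ...]
    operator_names: tuple[str, ...]
    covariates: np.ndarray  # shape (n_items, n_operators)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.covariates, index=pd.Index(self.item_ids, name="item_id"),
                            columns=list(self.operator_names))


def build_qmatrix(scheme: str, model_ids: Sequence[int] | None = None) -> QMatrix:
    """Return the (sub-)matrix of a built-in scheme for the given models."""
    key = str(scheme).lower()
    if key not in _SCHEMES:
        raise ValueError(
            f"unknown Q-matrix scheme {scheme!r}; available: {sorted(_SCHEMES)}")
    names, weights = _SCHEMES[key]
    if model_ids is None:
        model_ids = range(1, 14)
    mids = tuple(int(m) for m in model_ids)
    if any(not 1 <= m <= 13 for m in mids):
        raise ValueError("model ids must be in 1..13")
    w = np.array([weights[m - 1] for m in mids], dtype=int).reshape(len(mids), len(names))
    return QMatrix(scheme=key, model_ids=mids, operator_names=tuple(names), weights=w)


def from_frame(df: pd.DataFrame, scheme: str = "custom") -> QMatrix:
    """Build a custom QMatrix from a DataFrame indexed by model id."""
    return QMatrix(scheme=scheme, model_ids=tuple(int(m) for m in df.index),
                   operator_names=tuple(str(c) for c in df.columns),
                   weights=df.to_numpy(dtype=int))


def expand_item_properties(
    q: QMatrix, assignments: Sequence[tuple[str, int]]
) -> ItemPropertyMatrix:
    """Long-form item property matrix from (item_id, model_id) assignments."""
    rows, item_ids, model_ids = [], [], []
    for item_id, mid in assignments:
        mid = int(mid)
        if mid not in q.model_ids:
            raise ValueError(f"item {item_id!r}: model {mid} not in Q-matrix")
        rows.append(q.row(mid))
        item_ids.append(str(item_id))
        model_ids.append(mid)
    return ItemPropertyMatrix(
        item_ids=tuple(item_ids), model_ids=tuple(model_ids),
        operator_names=q.operator_names,
        covariates=np.array(rows, dtype=int).reshape(len(rows), len(q.operator_names)))


def distinct_profiles(q: QMatrix) -> tuple[int, set[tuple[int, ...]]]:
    """Number and set of unique operator rows in a Q-matrix."""
    if len(q.model_ids) == 0:
        raise ValueError("Q-matrix is empty")
    profiles = {tuple(int(x) for x in row) for row in q.weights}
    return len(profiles), profiles


def check_nesting(q_parent: QMatrix, q_child: QMatrix, tol: float = 1e-8) -> bool:
    """Is every child column a linear combination of the parent's columns?

    Least-squares residual test on the integer matrices; ``tol`` only guards
    float arithmetic.  Requires both matrices over the same models in the
    same order.
    """
    if q_parent.model_ids != q_child.model_ids:
        raise ValueError("Q-matrices must cover the same models in the same order")
    A = q_parent.weights.astype(float)
    B = q_child.weights.astype(float)
    coef, *_ = np.linalg.lstsq(A, B, rcond=None)
    resid = A @ coef - B
    return bool(np.abs(resid).max() < tol)
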