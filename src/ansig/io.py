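"""File formats: item banks (JSON), responses and Q-matrices (CSV), fits (JSON).

All formats are plain text and round-trip losslessly.  Responses are stored
persons x items with an empty cell meaning "not administered"; schema
violations are reported with the offending cell or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .items import ItemBank
from .lltm import LLTMFit
from .qmatrix import QMatrix, from_frame
from .rasch import RaschFit, ResponseMatrix

__all__ = [
    "read_item_bank", "write_item_bank",
    "read_responses", "write_responses",
    "read_qmatrix", "write_qmatrix",
    "read_fit", "write_fit",
]


def write_item_bank(bank: ItemBank, path) -> None:
    Path(path).write_text(bank.to_json())


def read_item_bank(path) -> ItemBank:
    bank = ItemBank.from_json(Path(path).read_text())
    ids = [it.item_id for it in bank.items]
    dup = {i for i in ids if ids.count(i) > 1 and i is not None}
    if dup:
        raise ValueError(f"{path}: duplicate item ids {sorted(dup)}")
    return bank


def write_responses(responses: ResponseMatrix, path) -> None:
    df = responses.scores.copy()
    df.index.name = "person_id"
    # integers where present, empty cells where not administered
    df.astype("Int64").to_csv(path)


def read_responses(path) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0).astype(float)
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~(np.isnan(arr) | np.isin(arr, (0.0, 1.0))))
    if bad.size:
        v, j = bad[0]
        raise ValueError(
            f"{path}: invalid score {arr[v, j]!r} at person {df.index[v]!r}, "
            f"item {df.columns[j]!r}")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated person or item ids")
    df.index.name = None
    return ResponseMatrix(df)


def write_qmatrix(q: QMatrix, path) -> None:
    q.to_frame().to_csv(path)


def read_qmatrix(path, scheme: str = "custom") -> QMatrix:
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: Q-matrix entries must be non-negative")
    return from_frame(df, scheme=scheme)


def write_fit(fit, path) -> None:
    if isinstance(fit, RaschFit):
        payload = {
            "type": "rasch_cml",
            "difficulties": fit.difficulties.to_dict(),
            "se": fit.se.to_dict(),
            "cond_loglik": fit.cond_loglik,
            "excluded_items": list(fit.excluded_items),
            "convergence": fit.convergence,
            "center": fit.center,
        }
    elif isinstance(fit, LLTMFit):
        payload = {
            "type": fit.model,
            "intercept": fit.intercept,
            "eta": fit.eta.to_dict(),
            "se_eta": fit.se_eta.to_dict(),
            "person_var": fit.person_var,
            "item_resid_var": fit.item_resid_var,
            "marg_loglik": fit.marg_loglik,
            "n_params": fit.n_params,
            "n_obs": fit.n_obs,
            "fitted_difficulties": fit.fitted_difficulties.to_dict(),
        }
    else:
        raise TypeError(f"cannot serialise fit of type {type(fit).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def read_fit(path) -> dict:
    """Load a fit file as a plain dict (type tag under ``"type"``)."""
    d = json.loads(Path(path).read_text())
    if "type" not in d:
        raise ValueError(f"{path}: missing fit type tag")
    return d
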