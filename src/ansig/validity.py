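"""Agreement and attenuation utilities for validity reporting."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["AgreementReport", "difficulty_agreement", "disattenuate"]


@dataclasses.dataclass
class AgreementReport:
    """Pearson agreement between two sets of paired item estimates."""

    pearson_r: float
    r_squared: float
    n_pairs: int
    pairs: pd.DataFrame


def difficulty_agreement(est_a, est_b) -> AgreementReport:
    """Pearson correlation (and its square) over paired estimates.

    Inputs may be pandas Series (matched on index) or equal-length
    sequences.
    """
    if isinstance(est_a, pd.Series) and isinstance(est_b, pd.Series):
        df = pd.concat([est_a.rename("a"), est_b.rename("b")], axis=1, join="inner")
        if len(df) < len(est_a) or len(df) < len(est_b):
            raise ValueError("item ids of the two estimate sets do not match")
    else:
        a, b = np.asarray(est_a, float), np.asarray(est_b, float)
        if a.shape != b.shape:
            raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
        df = pd.DataFrame({"a": a, "b": b})
    if len(df) < 3:
        raise ValueError("need at least 3 pairs")
    r = float(np.corrcoef(df["a"], df["b"])[0, 1])
    return AgreementReport(pearson_r=r, r_squared=r * r, n_pairs=len(df), pairs=df)


def disattenuate(r_xy: float, rel_x: float, rel_y: float) -> float:
    """Correct a correlation for unreliability: r / sqrt(rel_x * rel_y).

    The corrected value is capped at +-1 with a warning, which can occur
    when sample reliabilities underestimate the true ones.
    """
    for rel in (rel_x, rel_y):
        if not 0.0 < rel <= 1.0:
            raise ValueError(f"reliability must be in (0, 1], got {rel}")
    if abs(r_xy) > 1.0:
        raise ValueError(f"|correlation| must be <= 1, got {r_xy}")
    out = r_xy / np.sqrt(rel_x * rel_y)
    if abs(out) >= 1.0 and (rel_x < 1.0 or rel_y < 1.0):
        warnings.warn(f"disattenuated correlation {out:.3f} capped at +-1")
        out = float(np.sign(out))
    elif abs(out) > 1.0:
        out = float(np.sign(out))
    return float(out)
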