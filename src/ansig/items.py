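"""Rule-based generation and solving of number-series items.

Thirteen item models, each a template built from five cognitive operators
(apprehension of succession, parallel sequences, cluster formation,
non-progressive and progressive coefficient patterns), generate concrete
number-series items by substituting numeric values into a fixed rule.  Every
model also has a solver that infers the rule parameters back from a stem and
extrapolates the missing trailing elements, so generated items can be
round-trip verified.

Rule inference prefers the lowest-order rule family consistent with *all*
stem elements: constant difference < constant ratio < arithmetically
progressive differences < multiplicatively progressive differences (the
composite add-then-multiply step is algebraically identical to the latter and
yields the same extrapolation).
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np

from .qmatrix import ANSIG_OPERATORS, ANSIG_WEIGHTS

__all__ = [
    "OperatorProfile",
    "Item",
    "ItemBank",
    "GeneratorConfig",
    "InvalidModelError",
    "ItemGenerationError",
    "UnsolvableItemError",
    "AmbiguousItemError",
    "MODEL_IDS",
    "model_layout",
    "operator_profile",
    "generate_item",
    "solve_item",
    "verify_item",
    "sample_item_bank",
]

MODEL_IDS = tuple(range(1, 14))

#: (full sequence length, number of trailing blanks) per item model.  Model 12
#: has two printed layouts; this is the default (paired) one.
MODEL_LAYOUTS = {
    1: (5, 1),
    2: (6, 1),
    3: (6, 1),
    4: (8, 2),
    5: (9, 2),
    6: (6, 1),
    7: (6, 1),
    8: (6, 1),
    9: (7, 1),
    10: (11, 2),
    11: (8, 2),
    12: (9, 2),
    13: (10, 2),
}

#: Alternative model-12 layout: ten elements with the final subsequence-1
#: element blanked last, i.e. ... 110 (132) (4).
MODEL12_TABLE_LAYOUT = (10, 2)


class InvalidModelError(ValueError):
    """Raised for an item-model id outside 1..13."""


class ItemGenerationError(RuntimeError):
    """Raised when no admissible item can be built from the given parameters."""


class UnsolvableItemError(ValueError):
    """Raised when a stem fits no admissible parameterization of the model."""


class AmbiguousItemError(ValueError):
    """Raised when a stem is too short to pin down a unique rule."""


class OperatorProfile(tuple):
    """Binary involvement flags of the five cognitive operators for a model."""

    __slots__ = ()

    def __new__(cls, aos, ps, cf, npcp, pcp):
        return super().__new__(cls, (int(aos), int(ps), int(cf), int(npcp), int(pcp)))

    aos = property(lambda self: self[0])
    ps = property(lambda self: self[1])
    cf = property(lambda self: self[2])
    npcp = property(lambda self: self[3])
    pcp = property(lambda self: self[4])

    def __repr__(self):  # pragma: no cover - cosmetic
        return "OperatorProfile(aos=%d, ps=%d, cf=%d, npcp=%d, pcp=%d)" % self


def _check_model_id(model_id: int) -> int:
    if not isinstance(model_id, (int, np.integer)) or not 1 <= int(model_id) <= 13:
        raise InvalidModelError(f"item model id must be in 1..13, got {model_id!r}")
    return int(model_id)


def operator_profile(model_id: int) -> OperatorProfile:
    """Return the cognitive-operator profile (Q-matrix row) of a model."""
    mid = _check_model_id(model_id)
    return OperatorProfile(*ANSIG_WEIGHTS[mid - 1])


def model_layout(model_id: int, *, model12_layout: str = "paired") -> tuple[int, int]:
    """(full length, number of trailing blanks) convention for a model."""
    mid = _check_model_id(model_id)
    if mid == 12 and model12_layout == "table":
        return MODEL12_TABLE_LAYOUT
    return MODEL_LAYOUTS[mid]


@dataclasses.dataclass(frozen=True)
class Item:
    """One concrete number-series item.

    ``stem`` holds the displayed elements; the ``n_blanks`` answers occupy the
    final positions of the full sequence and are stored in ``key`` in
    presentation order.
    """

    model_id: int
    stem: tuple[int, ...]
    n_blanks: int
    key: tuple[int, ...]
    params: dict
    profile: OperatorProfile
    item_id: str | None = None

    @property
    def sequence(self) -> tuple[int, ...]:
        return self.stem + self.key

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "model_id": self.model_id,
            "stem": list(self.stem),
            "n_blanks": self.n_blanks,
            "key": list(self.key),
            "params": dict(self.params),
            "profile": dict(zip(ANSIG_OPERATORS, self.profile)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Item":
        return cls(
            model_id=int(d["model_id"]),
            stem=tuple(int(x) for x in d["stem"]),
            n_blanks=int(d["n_blanks"]),
            key=tuple(int(x) for x in d["key"]),
            params=dict(d.get("params", {})),
            profile=operator_profile(int(d["model_id"])),
            item_id=d.get("item_id"),
        )


@dataclasses.dataclass
class ItemBank:
    """A collection of generated items plus the request that produced it."""

    items: list[Item]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def by_model(self, model_id: int) -> list[Item]:
        return [it for it in self.items if it.model_id == model_id]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def to_json(self) -> str:
        return json.dumps(
            {"metadata": self.metadata, "items": [it.to_dict() for it in self.items]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ItemBank":
        d = json.loads(text)
        return cls(items=[Item.from_dict(x) for x in d["items"]], metadata=d.get("metadata", {}))


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Generation constraints.

    magnitude_cap keeps element values small enough that examinees do not
    dismiss an item as hard on sight; max_retries bounds rejection sampling.
    """

    magnitude_cap: int = 10_000
    max_retries: int = 500
    model12_layout: str = "paired"  # "paired" (default) or "table"


DEFAULT_CONFIG = GeneratorConfig()


# --------------------------------------------------------------------------
# Rule families (exact integer/rational arithmetic)
# --------------------------------------------------------------------------

def _const_diff(seq: Sequence[int], n_more: int):
    if len(seq) < 2:
        return None
    d = seq[1] - seq[0]
    if any(seq[k + 1] - seq[k] != d for k in range(len(seq) - 1)):
        return None
    last = seq[-1]
    out = [last + d * (k + 1) for k in range(n_more)]
    return out, {"rule": "constant_difference", "d": d}


def _const_ratio(seq: Sequence[int], n_more: int):
    if len(seq) < 2 or any(x == 0 for x in seq):
        return None
    r = Fraction(seq[1], seq[0])
    if r == 1:
        return None
    if any(Fraction(seq[k + 1], seq[k]) != r for k in range(len(seq) - 1)):
        return None
    out, cur = [], Fraction(seq[-1])
    for _ in range(n_more):
        cur *= r
        if cur.denominator != 1:
            return None
        out.append(int(cur))
    return out, {"rule": "constant_ratio", "ratio": [r.numerator, r.denominator]}


def _arith_diffs(seq: Sequence[int], n_more: int):
    # differences form an arithmetic progression with non-zero increment
    if len(seq) < 4:
        return None
    d = [seq[k + 1] - seq[k] for k in range(len(seq) - 1)]
    inc = d[1] - d[0]
    if inc == 0:
        return None
    if any(d[k + 1] - d[k] != inc for k in range(len(d) - 1)):
        return None
    out, cur, cd = [], seq[-1], d[-1]
    for _ in range(n_more):
        cd += inc
        cur += cd
        out.append(cur)
    return out, {"rule": "progressive_difference", "d0": d[0], "increment": inc}


def _ratio_diffs(seq: Sequence[int], n_more: int):
    # differences form a geometric progression; equivalent to the composite
    # step x <- (x + a) * b with b the difference ratio and a = x1/b - x0
    if len(seq) < 4:
        return None
    d = [seq[k + 1] - seq[k] for k in range(len(seq) - 1)]
    if any(x == 0 for x in d):
        return None
    b = Fraction(d[1], d[0])
    if b == 1:
        return None
    if any(Fraction(d[k + 1], d[k]) != b for k in range(len(d) - 1)):
        return None
    out, cur, cd = [], Fraction(seq[-1]), Fraction(d[-1])
    for _ in range(n_more):
        cd *= b
        cur += cd
        if cur.denominator != 1:
            return None
        out.append(int(cur))
    a = Fraction(seq[1], b) - seq[0] if b != 0 else None
    params = {"rule": "composite_step", "b": [b.numerator, b.denominator]}
    if a is not None and a.denominator == 1:
        params["a"] = int(a)
    return out, params


_FULL_HIERARCHY = (_const_diff, _const_ratio, _arith_diffs, _ratio_diffs)


def _extend(seq: Sequence[int], n_more: int, families: Iterable[Callable]) -> list[int]:
    seq = list(seq)
    if len(seq) < 2:
        raise AmbiguousItemError(
            f"subsequence {seq} is too short to identify a unique rule"
        )
    for fam in families:
        res = fam(seq, n_more)
        if res is not None:
            return res[0]
    raise UnsolvableItemError(f"no admissible rule extends subsequence {seq}")


# --------------------------------------------------------------------------
# Interleaved / patterned position helpers
# --------------------------------------------------------------------------

def _solve_interleaved(stem, n_blanks, full_len, families) -> list[int]:
    """Two alternating subsequences; blanks are the final positions."""
    if len(stem) + n_blanks != full_len:
        raise UnsolvableItemError(
            f"stem length {len(stem)} + {n_blanks} blanks != expected {full_len}"
        )
    full_idx = list(range(full_len))
    sub = {0: [i for i in full_idx if i % 2 == 0], 1: [i for i in full_idx if i % 2 == 1]}
    known = {s: [stem[i] for i in idx if i < len(stem)] for s, idx in sub.items()}
    ext = {}
    for s in (0, 1):
        missing = sum(1 for i in sub[s] if i >= len(stem))
        ext[s] = _extend(known[s], missing, families) if missing else []
    answers = []
    counters = {0: 0, 1: 0}
    for pos in range(len(stem), full_len):
        s = pos % 2
        answers.append(ext[s][counters[s]])
        counters[s] += 1
    return answers


def _pattern_s1s2s2(full_len: int) -> tuple[list[int], list[int]]:
    """Positions of subsequence 1 vs subsequence 2 under the S1 S2 S2 pattern."""
    s1 = [i for i in range(full_len) if i % 3 == 0]
    s2 = [i for i in range(full_len) if i % 3 != 0]
    return s1, s2


# --------------------------------------------------------------------------
# Per-model solvers
# --------------------------------------------------------------------------

def _solve_m1(stem, n_blanks):
    return _extend(stem, n_blanks, (_const_diff,))


def _solve_m2(stem, n_blanks):
    full = len(stem) + n_blanks
    if full % 2:
        raise UnsolvableItemError("cluster items need an even full length")
    g = full // 2
    if len(stem) < g + 1:
        raise AmbiguousItemError("second cluster entirely missing")
    v1, v2 = stem[0], stem[g]
    if any(x != v1 for x in stem[:g]) or any(x != v2 for x in stem[g:]):
        raise UnsolvableItemError(f"stem {list(stem)} is not two equal-size clusters")
    if v1 == v2:
        raise UnsolvableItemError("cluster values must differ between groups")
    return [v2] * n_blanks


def _solve_m3(stem, n_blanks):
    return _extend(stem, n_blanks, (_const_diff, _const_ratio))


def _solve_m4(stem, n_blanks):
    return _solve_interleaved(stem, n_blanks, len(stem) + n_blanks, (_const_diff,))


def _solve_m5(stem, n_blanks):
    return _solve_interleaved(
        stem, n_blanks, len(stem) + n_blanks, (_const_diff, _const_ratio)
    )


def _solve_m6(stem, n_blanks):
    return _extend(stem, n_blanks, _FULL_HIERARCHY)


_solve_m7 = _solve_m6


def _solve_m8(stem, n_blanks):
    full = len(stem) + n_blanks
    if full % 2:
        raise UnsolvableItemError("paired items need an even full length")
    pairs = [(stem[i], stem[i + 1]) for i in range(0, len(stem) - 1, 2)]
    complete = [b - a for a, b in pairs]
    if not complete:
        raise AmbiguousItemError("no complete pair in stem")
    d = complete[0]
    if any(x != d for x in complete):
        raise UnsolvableItemError("within-pair differences are not constant")
    if len(stem) % 2 == 0:
        raise UnsolvableItemError("stem must end mid-pair for a single blank")
    if n_blanks != 1:
        raise UnsolvableItemError("paired-group items take exactly one blank")
    return [stem[-1] + d]


def _solve_m9(stem, n_blanks):
    if len(stem) < 3:
        raise AmbiguousItemError("two-predecessor rule needs at least 3 elements")
    if any(stem[k] + stem[k + 1] != stem[k + 2] for k in range(len(stem) - 2)):
        raise UnsolvableItemError("stem does not follow the two-predecessor sum rule")
    seq = list(stem)
    for _ in range(n_blanks):
        seq.append(seq[-1] + seq[-2])
    return seq[len(stem):]


def _solve_m10(stem, n_blanks):
    return _solve_interleaved(stem, n_blanks, len(stem) + n_blanks, _FULL_HIERARCHY)


def _solve_m11(stem, n_blanks):
    if len(stem) < 4 or len(stem) % 2:
        raise UnsolvableItemError("alternating-chain items need an even stem of >= 4")
    d = stem[1] - stem[0]
    for i in range(2, len(stem) - 1, 2):
        if stem[i + 1] - stem[i] != d:
            raise UnsolvableItemError("within-pair differences are not constant")
    if any(stem[i] == 0 for i in range(1, len(stem), 2)):
        raise UnsolvableItemError("zero element breaks the multiplicative link")
    m = Fraction(stem[2], stem[1])
    for i in range(3, len(stem) - 1, 2):
        if Fraction(stem[i + 1], stem[i]) != m:
            raise UnsolvableItemError("cross-pair ratios are not constant")
    out, last = [], Fraction(stem[-1])
    for k in range(n_blanks):
        if k % 2 == 0:
            last = last * m
        else:
            last = last + d
        if last.denominator != 1:
            raise UnsolvableItemError("non-integer extrapolation")
        out.append(int(last))
    return out


def _solve_s1s2s2(stem, n_blanks, *, s2_linked: bool):
    """Shared solver for models 12 (linked pairs) and 13 (unrelated pairs)."""
    full = len(stem) + n_blanks
    s1_pos, s2_pos = _pattern_s1s2s2(full)
    s1_known = [stem[i] for i in s1_pos if i < len(stem)]
    s2_known = [stem[i] for i in s2_pos if i < len(stem)]
    if len(s2_known) < 2:
        raise AmbiguousItemError("paired subsequence has fewer than two elements")
    # within-pair difference from consecutive pair members (s2 indices 0-1, 2-3, ...)
    w = None
    for j in range(0, len(s2_known) - 1, 2):
        diff = s2_known[j + 1] - s2_known[j]
        if w is None:
            w = diff
        elif diff != w:
            raise UnsolvableItemError("within-pair differences are not constant")
    if w is None:
        raise AmbiguousItemError("no complete pair in the paired subsequence")
    b = None
    if s2_linked:
        for j in range(1, len(s2_known) - 1, 2):
            diff = s2_known[j + 1] - s2_known[j]
            if b is None:
                b = diff
            elif diff != b:
                raise UnsolvableItemError("between-pair differences are not constant")
        if b is None:
            raise AmbiguousItemError("pair linkage not observable in stem")
    answers = []
    s1_seq = list(s1_known)
    s2_seq = list(s2_known)
    for pos in range(len(stem), full):
        if pos in s1_pos:
            val = _extend(s1_seq, 1, _FULL_HIERARCHY)[0]
            s1_seq.append(val)
        else:
            j = len(s2_seq)  # next s2 index
            if j % 2 == 1:  # completing a pair
                val = s2_seq[-1] + w
            elif s2_linked:
                val = s2_seq[-1] + b
            else:
                raise UnsolvableItemError(
                    "cannot extrapolate the start of an unrelated pair"
                )
            s2_seq.append(val)
        answers.append(val)
    return answers


def _solve_m12(stem, n_blanks):
    return _solve_s1s2s2(stem, n_blanks, s2_linked=True)


def _solve_m13(stem, n_blanks):
    return _solve_s1s2s2(stem, n_blanks, s2_linked=False)


_SOLVERS = {
    1: _solve_m1, 2: _solve_m2, 3: _solve_m3, 4: _solve_m4, 5: _solve_m5,
    6: _solve_m6, 7: _solve_m7, 8: _solve_m8, 9: _solve_m9, 10: _solve_m10,
    11: _solve_m11, 12: _solve_m12, 13: _solve_m13,
}


def solve_item(model_id: int, stem: Sequence[int], n_blanks: int) -> list[int]:
    """Infer the model's rule from ``stem`` and return the ``n_blanks`` answers.

    Answers are returned in presentation order (the final positions of the
    full sequence).  Raises :class:`UnsolvableItemError` if the stem fits no
    admissible parameterization and :class:`AmbiguousItemError` if it is too
    short to identify the rule.
    """
    mid = _check_model_id(model_id)
    if n_blanks not in (1, 2):
        raise ValueError(f"n_blanks must be 1 or 2, got {n_blanks}")
    stem = [int(x) for x in stem]
    return [int(v) for v in _SOLVERS[mid](stem, n_blanks)]


# --------------------------------------------------------------------------
# Per-model builders and samplers
# --------------------------------------------------------------------------
# Builders turn an explicit parameter map into the full sequence; samplers
# draw admissible parameters.  Magnitudes are kept deliberately small.

_OP_ALIASES = {
    "+": "+", "add": "+", "-": "-", "−": "-", "sub": "-",
    "*": "*", "x": "*", "×": "*", "mul": "*",
    "/": "/", "÷": "/", "div": "/",
}


def _chain(start: int, op: str, coef: int, length: int) -> list[int]:
    op = _OP_ALIASES.get(str(op), None)
    if op is None:
        raise ItemGenerationError(f"unknown operator {op!r}")
    if op == "/":
        # build a multiplicative chain backwards so every division is exact
        seq = [start * coef ** k for k in range(length)]
        return seq[::-1]
    seq = [start]
    for _ in range(length - 1):
        x = seq[-1]
        seq.append(x + coef if op == "+" else x - coef if op == "-" else x * coef)
    return seq


def _build_m1(p):
    length = p.get("length", MODEL_LAYOUTS[1][0])
    c = p["constant"]
    if c not in (1, 10, 100):
        raise ItemGenerationError("model 1 constant must be 1, 10 or 100")
    return [p["start"] + k * c for k in range(length)]


def _sample_m1(rng):
    return {"start": int(rng.integers(0, 101)),
            "constant": int(rng.choice([1, 10, 100]))}


def _build_m2(p):
    g = p.get("group_size", 3)
    vals = p["values"]
    v1, v2 = (sorted(vals) if isinstance(vals, (set, frozenset)) else list(vals))[:2]
    if v1 == v2:
        raise ItemGenerationError("model 2 group values must be distinct")
    return [v1] * g + [v2] * g


def _sample_m2(rng):
    v1 = int(rng.integers(1, 100))
    v2 = int(rng.integers(1, 100))
    while v2 == v1:
        v2 = int(rng.integers(1, 100))
    return {"values": (v1, v2), "group_size": 3}


def _build_m3(p):
    length = p.get("length", MODEL_LAYOUTS[3][0])
    seq = _chain(p["start"], p["op"], p["coef"], length)
    if len(set(seq)) != len(seq):
        raise ItemGenerationError("model 3 chain must not repeat values")
    return seq


def _sample_m3(rng):
    return {"start": int(rng.integers(1, 11)),
            "op": str(rng.choice(["+", "-", "*", "/"])),
            "coef": int(rng.integers(2, 10))}


def _interleave(a: Sequence[int], b: Sequence[int]) -> list[int]:
    out = []
    for k in range(len(a) + len(b)):
        out.append(a[k // 2] if k % 2 == 0 else b[k // 2])
    return out


def _build_m4(p):
    a = _build_m1({"start": p["start_a"], "constant": p["constant_a"], "length": 4})
    b = _build_m1({"start": p["start_b"], "constant": p["constant_b"], "length": 4})
    if a == b:
        raise ItemGenerationError("model 4 subsequences must differ")
    return _interleave(a, b)


def _sample_m4(rng):
    pa, pb = _sample_m1(rng), _sample_m1(rng)
    return {"start_a": pa["start"], "constant_a": pa["constant"],
            "start_b": pb["start"], "constant_b": pb["constant"]}


def _build_m5(p):
    a = _chain(p["start_a"], p["op_a"], p["coef_a"], 5)
    b = (_chain(p["start_b"], p["op_b"], p["coef_b"], 4)
         if "op_b" in p else
         [p["start_b"] + k * p["constant_b"] for k in range(4)])
    if a[:4] == b:
        raise ItemGenerationError("model 5 subsequences must differ")
    return _interleave(a, b)


def _sample_m5(rng):
    p = {"start_a": int(rng.integers(1, 11)),
         "op_a": str(rng.choice(["+", "*"])),
         "coef_a": int(rng.integers(2, 10))}
    if rng.random() < 0.5:
        p.update({"start_b": int(rng.integers(1, 11)),
                  "op_b": str(rng.choice(["+", "*"])),
                  "coef_b": int(rng.integers(2, 10))})
    else:
        p.update({"start_b": int(rng.integers(0, 101)),
                  "constant_b": int(rng.choice([1, 10, 100]))})
    return p


def _build_m6(p):
    length = p.get("length", MODEL_LAYOUTS[6][0])
    if p["incr"] == 0:
        raise ItemGenerationError("model 6 increment must be non-zero")
    seq, d = [p["start"]], p["d0"]
    for _ in range(length - 1):
        seq.append(seq[-1] + d)
        d += p["incr"]
    return seq


def _sample_m6(rng):
    return {"start": int(rng.integers(1, 11)), "d0": int(rng.integers(1, 6)),
            "incr": int(rng.choice([1, 2, 3]))}


def _build_m7(p):
    length = p.get("length", MODEL_LAYOUTS[7][0])
    seq = [p["start"]]
    for _ in range(length - 1):
        seq.append((seq[-1] + p["a"]) * p["b"])
    return seq


def _sample_m7(rng):
    return {"start": int(rng.integers(1, 11)), "a": int(rng.integers(1, 6)),
            "b": int(rng.choice([2, 3]))}


def _build_m8(p):
    d = p["d"]
    anchors = list(p["anchors"])
    if len(anchors) != 3 or len(set(anchors)) != 3:
        raise ItemGenerationError("model 8 needs three distinct group anchors")
    seq = []
    for a in anchors:
        seq += [a, a + d]
    return seq


def _sample_m8(rng):
    anchors = []
    while len(anchors) < 3:
        a = int(rng.integers(1, 301))
        if a not in anchors:
            anchors.append(a)
    return {"anchors": tuple(anchors), "d": int(rng.integers(1, 10))}


def _build_m9(p):
    length = p.get("length", MODEL_LAYOUTS[9][0])
    seq = [p["seed1"], p["seed2"]]
    while len(seq) < length:
        seq.append(seq[-1] + seq[-2])
    return seq


def _sample_m9(rng):
    return {"seed1": int(rng.integers(1, 10)), "seed2": int(rng.integers(1, 10))}


def _build_m10(p):
    a = _build_m6({"start": p["start_a"], "d0": p["d0_a"], "incr": p["incr_a"],
                   "length": 6})
    b = [p["start_b"] + k * p["constant_b"] for k in range(5)]
    return _interleave(a, b)


def _sample_m10(rng):
    return {"start_a": int(rng.integers(1, 11)), "d0_a": int(rng.integers(1, 6)),
            "incr_a": int(rng.choice([1, 2, 3])),
            "start_b": int(rng.integers(1, 31)), "constant_b": int(rng.integers(1, 10))}


def _build_m11(p):
    length = p.get("length", MODEL_LAYOUTS[11][0])
    seq = [p["start"]]
    for k in range(length - 1):
        seq.append(seq[-1] + p["d"] if k % 2 == 0 else seq[-1] * p["m"])
    return seq


def _sample_m11(rng):
    return {"start": int(rng.integers(1, 10)), "d": int(rng.integers(2, 10)), "m": 2}


def _s1s2s2_sequence(s1: Sequence[int], s2: Sequence[int], full_len: int) -> list[int]:
    s1_pos, _ = _pattern_s1s2s2(full_len)
    out, i1, i2 = [], 0, 0
    for pos in range(full_len):
        if pos in s1_pos:
            out.append(s1[i1]); i1 += 1
        else:
            out.append(s2[i2]); i2 += 1
    return out


def _build_m12(p, *, full_len=9):
    full_len = p.get("length", full_len)
    n1 = len(_pattern_s1s2s2(full_len)[0])
    s1 = [p["s1_start"] + k * p["s1_d"] for k in range(n1)]
    w, b = p["pair_d"], p.get("between_d", p["pair_d"])
    s2, cur = [], p["s2_start"]
    for k in range(full_len - n1):
        s2.append(cur)
        cur += w if k % 2 == 0 else b
    return _s1s2s2_sequence(s1, s2, full_len)


def _sample_m12(rng):
    return {"s1_start": int(rng.integers(1, 11)), "s1_d": int(rng.integers(1, 6)),
            "s2_start": int(rng.integers(1, 51)), "pair_d": int(rng.integers(2, 31)),
            "between_d": int(rng.integers(2, 31))}


def _build_m13(p):
    full_len = p.get("length", MODEL_LAYOUTS[13][0])
    n1 = len(_pattern_s1s2s2(full_len)[0])
    s1 = [p["s1_start"] + k * p["s1_d"] for k in range(n1)]
    anchors, w = list(p["anchors"]), p["pair_d"]
    if len(set(anchors)) != len(anchors):
        raise ItemGenerationError("model 13 pair anchors must be distinct")
    s2 = []
    for a in anchors:
        s2 += [a, a + w]
    return _s1s2s2_sequence(s1, s2[: full_len - n1], full_len)


def _sample_m13(rng):
    anchors = []
    while len(anchors) < 3:
        a = int(rng.integers(1, 301))
        if a not in anchors:
            anchors.append(a)
    return {"s1_start": int(rng.integers(1, 11)), "s1_d": int(rng.integers(1, 6)),
            "anchors": tuple(anchors), "pair_d": int(rng.integers(2, 10))}


_BUILDERS = {
    1: _build_m1, 2: _build_m2, 3: _build_m3, 4: _build_m4, 5: _build_m5,
    6: _build_m6, 7: _build_m7, 8: _build_m8, 9: _build_m9, 10: _build_m10,
    11: _build_m11, 12: _build_m12, 13: _build_m13,
}
_SAMPLERS = {
    1: _sample_m1, 2: _sample_m2, 3: _sample_m3, 4: _sample_m4, 5: _sample_m5,
    6: _sample_m6, 7: _sample_m7, 8: _sample_m8, 9: _sample_m9, 10: _sample_m10,
    11: _sample_m11, 12: _sample_m12, 13: _sample_m13,
}


def _build_full(model_id: int, params: dict, config: GeneratorConfig) -> list[int]:
    if model_id == 12 and "length" not in params and config.model12_layout == "table":
        params = dict(params, length=MODEL12_TABLE_LAYOUT[0])
    seq = _BUILDERS[model_id](params)
    cap = config.magnitude_cap
    if any(abs(x) > cap for x in seq):
        raise ItemGenerationError(
            f"model {model_id} sequence exceeds magnitude cap {cap}: {seq}"
        )
    return seq


def generate_item(
    model_id: int,
    params: dict | None = None,
    seed: int | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
    item_id: str | None = None,
) -> Item:
    """Generate one item from a model rule.

    With explicit ``params`` the item is built deterministically and parameter
    violations raise :class:`ItemGenerationError`.  Without ``params``,
    admissible parameters are drawn from the model's default ranges using
    ``seed`` (or ``rng``); draws breaking the magnitude cap or degeneracy
    guards are rejected and resampled up to ``config.max_retries`` times.
    """
    mid = _check_model_id(model_id)
    if params is not None:
        full = _build_full(mid, dict(params), config)
        used = dict(params)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        last_err = None
        for _ in range(config.max_retries):
            cand = _SAMPLERS[mid](rng)
            try:
                full = _build_full(mid, cand, config)
                used = cand
                break
            except ItemGenerationError as err:
                last_err = err
        else:
            raise ItemGenerationError(
                f"model {mid}: no admissible draw in {config.max_retries} tries"
            ) from last_err
    n_blanks = MODEL_LAYOUTS[mid][1]
    stem, key = tuple(full[:-n_blanks]), tuple(full[-n_blanks:])
    return Item(model_id=mid, stem=stem, n_blanks=n_blanks, key=key,
                params=used, profile=operator_profile(mid), item_id=item_id)


def verify_item(item: Item, explain: bool = False):
    """Round-trip check: does rule inference on the stem reproduce the key?"""
    try:
        answer = solve_item(item.model_id, item.stem, item.n_blanks)
    except (UnsolvableItemError, AmbiguousItemError, ValueError) as err:
        return (False, str(err)) if explain else False
    ok = tuple(answer) == tuple(item.key)
    if explain:
        return ok, ("ok" if ok else f"solver answer {answer} != key {list(item.key)}")
    return ok


def sample_item_bank(
    model_ids: Sequence[int],
    n_per_model: int,
    constraints: GeneratorConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> ItemBank:
    """Draw a reproducible bank with ``n_per_model`` distinct items per model.

    Per-item random streams are derived from the root seed by the counter
    scheme ``default_rng([seed, model_id, attempt])`` so any single item can
    be regenerated without replaying the whole bank.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    items: list[Item] = []
    for mid in model_ids:
        mid = _check_model_id(mid)
        stems_seen, attempt = set(), 0
        per_model: list[Item] = []
        while len(per_model) < n_per_model:
            if attempt >= constraints.max_retries + 10 * n_per_model:
                raise ItemGenerationError(
                    f"model {mid}: could not draw {n_per_model} distinct items"
                )
            rng = np.random.default_rng([seed, mid, attempt])
            attempt += 1
            try:
                it = generate_item(mid, rng=rng, config=constraints)
            except ItemGenerationError:
                continue
            if it.stem in stems_seen:
                continue
            stems_seen.add(it.stem)
            per_model.append(dataclasses.replace(
                it, item_id=f"m{mid:02d}_{len(per_model) + 1:02d}"))
        items.extend(per_model)
    meta = {"generator": "ansig", "seed": int(seed),
            "n_per_model": int(n_per_model),
            "model_ids": [int(m) for m in model_ids],
            "magnitude_cap": constraints.magnitude_cap}
    return ItemBank(items=items, metadata=meta)
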