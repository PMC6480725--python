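"""Respondent simulation and multi-form test assembly.

Responses are Bernoulli draws under the Rasch item characteristic curve,
P(x = 1) = logistic(theta_v - delta_i), with abilities drawn from a normal
distribution and, optionally, a per-item residual shift drawn once per item
(the item-error extension).  Non-administered cells are missing by design,
reproducing anchored multi-form layouts: the reference study design assigns
six item models to Form A (30 items) and seven to Form B (35 items) with the
ten model-3 and model-8 items shared as anchors.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rasch import ResponseMatrix

__all__ = [
    "FormDesign",
    "SimulationConfig",
    "STUDY_FORM_MODELS",
    "assemble_forms",
    "assemble_form_by_bins",
    "simulate_responses",
]

#: Item-model composition of the two study forms; models 3 and 8 are the anchors.
STUDY_FORM_MODELS = {
    "A": (3, 4, 6, 8, 10, 12),
    "B": (3, 5, 7, 8, 9, 11, 13),
}


@dataclasses.dataclass
class FormDesign:
    """Named test forms over a common item pool."""

    forms: dict[str, list[str]]            # form name -> ordered item ids
    anchors: list[str] = dataclasses.field(default_factory=list)
    assignment: str = "uniform"            # person -> form allocation rule

    def __post_init__(self):
        for name, ids in self.forms.items():
            if not ids:
                raise ValueError(f"form {name!r} is empty")
        if len(self.forms) > 1:
            bridged = set.intersection(*(set(v) for v in self.forms.values()))
            for a in self.anchors:
                if a not in bridged:
                    raise ValueError(f"anchor {a!r} is not in every form")
            if not self.anchors:
                warnings.warn("multiple forms without anchors are not linkable "
                              "on a common metric")

    @property
    def all_items(self) -> list[str]:
        seen, out = set(), []
        for ids in self.forms.values():
            for i in ids:
                if i not in seen:
                    seen.add(i)
                    out.append(i)
        return out


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for response simulation.

    Defaults mirror the reference design: 396 Form A and 174 Form B
    respondents, standard-normal abilities, no item residual (pure Rasch).
    """

    n_persons: Mapping[str, int] | int = dataclasses.field(
        default_factory=lambda: {"A": 396, "B": 174})
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    difficulties: Mapping[str, float] | None = None
    item_resid_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        if self.item_resid_sd < 0:
            raise ValueError("item_resid_sd must be non-negative")


def assemble_forms(
    item_models: Sequence[tuple[str, int]],
    form_models: Mapping[str, Sequence[int]] | None = None,
    anchor_models: Sequence[int] = (3, 8),
) -> FormDesign:
    """Build a form design from (item_id, model_id) pairs.

    The default specification reproduces the two-form study layout; pass a
    custom ``form_models`` mapping for other designs.  Items of the
    ``anchor_models`` that appear in every form become anchors.
    """
    if form_models is None:
        form_models = STUDY_FORM_MODELS
    by_model: dict[int, list[str]] = {}
    for iid, mid in item_models:
        by_model.setdefault(int(mid), []).append(str(iid))
    forms = {}
    for name, mids in form_models.items():
        ids = []
        for mid in mids:
            if mid not in by_model:
                raise ValueError(f"form {name!r} needs items of model {mid}, none given")
            ids.extend(by_model[mid])
        forms[name] = ids
    anchors = []
    if len(forms) > 1:
        shared = set.intersection(*(set(v) for v in forms.values()))
        anchors = [i for mid in anchor_models for i in by_model.get(mid, ())
                   if i in shared]
    return FormDesign(forms=forms, anchors=anchors)


def assemble_form_by_bins(
    difficulties: Mapping[str, float],
    bin_width: float = 0.5,
    difficulty_range: tuple[float, float] = (-2.0, 2.0),
    per_bin: int = 3,
    seed: int = 0,
    form_name: str = "C",
) -> FormDesign:
    """Draw a form by sampling items uniformly within difficulty bins.

    Within each ``bin_width``-logit interval of ``difficulty_range``,
    ``per_bin`` items are drawn without replacement; under-filled bins raise
    a warning and contribute what they have.  With the default settings on a
    pool spanning the range this yields a flat-information form.
    """
    if not difficulties:
        raise ValueError("empty difficulty list")
    ids = np.array(list(difficulties.keys()))
    vals = np.array([difficulties[i] for i in ids], dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = difficulty_range
    edges = np.arange(lo, hi + 1e-9, bin_width)
    chosen: list[str] = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        in_bin = ids[(vals >= b0) & (vals < b1)]
        if len(in_bin) < per_bin:
            warnings.warn(f"bin [{b0}, {b1}) has only {len(in_bin)} items")
            chosen.extend(in_bin)
        else:
            chosen.extend(rng.choice(in_bin, size=per_bin, replace=False))
    return FormDesign(forms={form_name: [str(i) for i in chosen]}, anchors=[])


def simulate_responses(config: SimulationConfig, design: FormDesign) -> ResponseMatrix:
    """Simulate a missing-by-design response matrix under the Rasch ICC.

    Abilities are Normal(theta_mean, theta_sd^2); when ``item_resid_sd > 0``
    each item's difficulty is shifted once by a Normal(0, item_resid_sd^2)
    draw before any person responds.  Persons are allocated to forms either
    by fixed counts (``n_persons`` mapping) or uniformly at random.
    """
    if config.difficulties is None:
        raise ValueError("difficulties must be supplied for all designed items")
    items = design.all_items
    missing = [i for i in items if i not in config.difficulties]
    if missing:
        raise ValueError(f"no difficulty supplied for items: {missing[:5]}")
    rng = np.random.default_rng(config.seed)
    delta = np.array([config.difficulties[i] for i in items], dtype=float)
    if config.item_resid_sd > 0:
        delta = delta + rng.normal(0.0, config.item_resid_sd, len(items))

    form_names = list(design.forms)
    if isinstance(config.n_persons, Mapping):
        alloc = [f for f in form_names for _ in range(int(config.n_persons[f]))]
    else:
        total = int(config.n_persons)
        alloc = list(rng.choice(form_names, size=total))
    n = len(alloc)
    theta = rng.normal(config.theta_mean, config.theta_sd, n)
    col = {iid: j for j, iid in enumerate(items)}
    X = np.full((n, len(items)), np.nan)
    for v, form in enumerate(alloc):
        idx = np.array([col[i] for i in design.forms[form]])
        p = 1.0 / (1.0 + np.exp(-(theta[v] - delta[idx])))
        X[v, idx] = (rng.random(idx.size) < p).astype(float)
    pids = [f"p{v+1}_{alloc[v]}" for v in range(n)]
    return ResponseMatrix.from_array(X, person_ids=pids, item_ids=items)
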