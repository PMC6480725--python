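"""Explain and predict item difficulty from cognitive-operator weights.

Fits the LLTM and the LLTM-plus-error to simulated study-like responses,
compares the models, and predicts per-model difficulty for new items from
the reference coefficient set alone (no response data needed).
"""

import numpy as np

from ansig import (ResponseMatrix, build_qmatrix, compare_models,
                   expand_item_properties, fit_lltm, fit_lltm_error,
                   predict_difficulties)
from ansig.reference import LLTM_COEFFICIENTS

q = build_qmatrix("ansig", range(3, 14))
items = [(f"m{m:02d}_{j+1}", m) for m in range(3, 14) for j in range(5)]
props = expand_item_properties(q, items)

# simulate respondents whose difficulties follow the operator decomposition
rng = np.random.default_rng(3)
easiness = LLTM_COEFFICIENTS["intercept"] + props.covariates @ np.array(
    list(LLTM_COEFFICIENTS["eta"].values()))
theta = rng.normal(0, 1.09, 500)
p = 1 / (1 + np.exp(-(theta[:, None] + easiness[None, :])))
rm = ResponseMatrix.from_array((rng.random(p.shape) < p).astype(float),
                               item_ids=[i for i, _ in items])

fit = fit_lltm(rm, props)
print("LLTM operator easiness coefficients (negative = harder):")
for name, value in fit.eta.items():
    print(f"  {name:>5}: {value:+.2f}  (SE {fit.se_eta[name]:.2f})")
print(f"  intercept {fit.intercept:.2f}, person variance {fit.person_var:.2f}")

err = fit_lltm_error(rm, props, se=False)
print(f"\nLLTM+error item residual variance: {err.item_resid_var:.2f} "
      "(0 here: difficulties were generated exactly from the operators)")
cmp = compare_models([fit, err], nested_pairs=[(0, 1)])
print(cmp.table.round(1))

pred = predict_difficulties(LLTM_COEFFICIENTS, q)
print("\npredicted difficulty per item model from the reference coefficients:")
print(pred.round(2).to_string())
# A model's prediction is the negated sum of the intercept and its operators'
# easiness coefficients: more (and harder) operators give harder items.
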