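"""Agreement between calibration methods and attenuation-corrected validity.

Correlates the reference Rasch difficulties with the operator-predicted
ones, then corrects the external-test correlations for unreliability of
both measures.
"""

from ansig import difficulty_agreement, disattenuate
from ansig.reference import (EXTERNAL_TEST, PERSON_SEPARATION,
                             reference_items)

ref = reference_items()
rep = difficulty_agreement(ref["rasch"], ref["lltm"])
print(f"Rasch vs operator-predicted difficulty over {rep.n_pairs} items: "
      f"r = {rep.pearson_r:.2f}, R^2 = {rep.r_squared:.2f}")
# the operators explain about two thirds of the difficulty variance

alpha = EXTERNAL_TEST["alpha"]
for form, rel in PERSON_SEPARATION.items():
    raw = EXTERNAL_TEST["r_form"][form]
    corrected = disattenuate(raw, rel, alpha)
    print(f"Form {form}: external correlation {raw:.2f} -> "
          f"{corrected:.2f} after correcting for reliabilities "
          f"({rel:.2f}, {alpha:.2f})")
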