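"""Assemble a flat-information form by difficulty-binned random draws.

Takes the 49 reference item difficulties, draws up to three items from each
half-logit bin between -2 and 2, and compares the resulting form's
information curve with the two original forms.
"""

from ansig import assemble_form_by_bins, test_information
from ansig.reference import reference_difficulties

pool = {str(i): d for i, d in reference_difficulties(column="rasch").items()}

for form in ("A", "B"):
    deltas = reference_difficulties(form=form)
    ti = test_information(deltas)
    print(f"Form {form} ({len(deltas)} items): max information "
          f"{ti.max_info:.2f} at theta = {ti.argmax_theta:.1f}")

design = assemble_form_by_bins(pool, bin_width=0.5, difficulty_range=(-2, 2),
                               per_bin=3, seed=1)
chosen = [pool[i] for i in design.forms["C"]]
ti = test_information(chosen)
print(f"Form C ({len(chosen)} items): max information {ti.max_info:.2f} "
      f"at theta = {ti.argmax_theta:.1f}")
# Form C trades Form B's sharp peak for a wider, flatter curve centred near
# average ability — fewer items, more even measurement precision.
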