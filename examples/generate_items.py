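"""Generate number-series items from the thirteen rule-based item models.

Draws a small bank, prints one item per model with its solved answer, and
round-trip verifies every item (the solver must re-derive each key from the
stem alone).
"""

from ansig import sample_item_bank, solve_item, verify_item

bank = sample_item_bank(model_ids=range(1, 14), n_per_model=3, seed=7)
print(f"bank of {len(bank)} items (3 per model), seed 7\n")

for model_id in range(1, 14):
    item = bank.by_model(model_id)[0]
    stem = " ".join(str(x) for x in item.stem)
    key = " ".join(f"({x})" for x in item.key)
    solved = solve_item(item.model_id, item.stem, item.n_blanks)
    print(f"model {model_id:>2}: {stem} {key}   solver -> {solved}")

ok = sum(verify_item(it) for it in bank)
print(f"\nround-trip verified: {ok}/{len(bank)}")
# Each line shows a generated stem with its key in parentheses; the solver
# output must equal the key, which the final count confirms for the bank.
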