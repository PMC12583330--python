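"""Suspect-list clean-up cascade on a synthetic table.

Generates a 200-row suspect table with planted defects (residual
salts, sub-40 Da and over-1000 Da masses, >200-atom molecules,
dications, duplicate structures), runs the MS-ready cascade —
desalt, neutralize, canonicalize, filter, deduplicate — and shows
that every planted defect lands in its rejection class.
"""

from speclib import clean_table, generate_compound_table

fractions = {"salt": 0.06, "sub40": 0.04, "over1000": 0.04,
             "over200atoms": 0.02, "multicharged": 0.03, "duplicate": 0.06}
records, truth = generate_compound_table(200, fractions, seed=17)
result = clean_table(records)

planted = {cls: sum(1 for v in truth.values() if v == cls) for cls in set(truth.values())}
print(f"input records: {result.n_input}")
for reason, count in result.summary.items():
    if reason not in ("input", "kept") and count:
        print(f"  rejected {reason:<16} {count}")
print(f"MS-ready compounds kept: {len(result.compounds)} "
      f"(planted clean: {planted['keep']})")
print(f"ion-species groups: {result.ion_groups()}")
print("conservation holds:",
      len(result.compounds) + len(result.rejections) == result.n_input)
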