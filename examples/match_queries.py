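"""Annotate degraded query spectra against an in-silico library.

Builds a stub-predicted library for 50 synthetic compounds, corrupts
each positive-mode 20 eV spectrum the way real acquisitions degrade
(ppm jitter, intensity noise, dropout, chimeric contaminant peaks),
and matches the corrupted queries back under the in-silico threshold
profile (cosine >= 0.2, explained intensity >= 0.7, >= 2 matched
fragments including the precursor, 3/5 ppm tolerances).
"""

from speclib import (
    PROFILES, CorruptionConfig, StubPredictor, annotate, clean_table,
    complete_metadata, corrupt_spectrum, generate_compound_table, predict_spectra,
)
from speclib.spectra import SpectralLibrary

records, _ = generate_compound_table(50, {}, seed=23)
compounds = clean_table(records).compounds
library, _ = predict_spectra(compounds, StubPredictor(seed=23))
library = complete_metadata(library, compounds)

queries = SpectralLibrary(
    corrupt_spectrum(s, CorruptionConfig(seed=29))
    for s in library
    if s.collision_energy == 20.0 and s.polarity == "positive"
)

table = annotate(queries, library, PROFILES["in_silico"])
top = table[table["rank"] == 1]
correct = (top.query_id == top.reference_id).mean()
print(table.head(5).to_string(index=False))
print(f"\n{len(queries)} queries, {len(table)} reported annotations")
print(f"true compound ranked first for {correct:.0%} of queries")
print(f"verdicts: {top.verdict.value_counts().to_dict()}")
print("cosine dips under corruption but reference-side explained intensity "
      "stays high - the signature of interference, not mis-annotation")
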