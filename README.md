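# speclib

Suspect screening by LC-HRMS lives or dies by spectral libraries: a
detected MS2 feature can only be annotated if some library — measured
or predicted — contains a comparable spectrum. `speclib` is a toolkit
for the in-silico side of that workflow. It turns a suspect-list
compound table (thousands of SMILES with assorted identifiers, salts,
charged species and duplicates included) into an MS-ready spectral
library built around a pluggable fragmentation predictor, stores it as
NIST MSP text and as an SQLite database, and annotates query MS2
spectra against it with the scoring and decision rules suited to
predicted spectra.

It is written for environmental and exposomics mass spectrometrists
who want to screen beyond the chemical space of experimental reference
libraries, and for method developers who need a testable, deterministic
harness around every stage of that pipeline.

## What it computes

**MS-ready preparation** (`speclib.chem`): desalting (counter-ion
stripping), rule-based charge neutralization, RDKit canonicalization,
then a fixed filter cascade — monoisotopic mass < 40 Da, > 1000 Da,
more than 200 atoms, |charge| ≥ 2 — and duplicate merging by canonical
SMILES string comparison. Every input row ends as exactly one MS-ready
compound or one reasoned rejection, so counts always conserve.
Neutrals are assigned [M+H]⁺ and [M−H]⁻ species, native ions [M]⁺ or
[M]⁻ (electron-mass corrected).

**Library building** (`speclib.build`, `speclib.msp`, `speclib.db`): a
predictor contract `(SMILES, adduct) → {10, 20, 40 eV peak lists}` with
a deterministic stub implementation and an external-process adapter; a
tolerant MSP reader/writer (key synonyms, `Num Peaks` repair); an
mzVault-style SQLite schema with one compound row per structure and
one spectrum row per collision energy.

**Matching** (`speclib.match`): precursor prefilter (3 ppm), greedy
one-to-one peak alignment at 5 ppm with unmatched peaks kept and
matched to zero, then the unweighted cosine

    cos θ = v · u / (|v| |u|)

on the aligned intensity vectors, the explained intensity (fraction of
reference intensity carried by matched peaks), and the matched-fragment
count including the precursor ion. Decisions are dual-threshold:
profile `experimental` (cosine ≥ 0.7, explained intensity ≥ 0.9) for
measured libraries, `in_silico` (cosine ≥ 0.2, explained intensity
≥ 0.7) for predicted ones, both requiring ≥ 2 matched fragments.

**Validation** (`speclib.validate`): score percentiles (type-7),
score-bin counts (≥ 0.7 / 0.1–0.7 / < 0.1), threshold sweeps against
ground-truth labels, and feature-level overlap between library kinds.

**Synthetic data** (`speclib.simulate`): seeded generators for suspect
tables with planted defects, centroided reference spectra, and query
corruption (ppm jitter, intensity noise, dropout, chimeric peaks), so
the whole pipeline is testable offline.

## Worked example

`examples/` holds one short script per capability. Exact-mass adduct
calculation (`python examples/compute_adduct_mz.py`):

```
hexafluoropropane-2,2-diol   M        = 183.99590 Da
  [M-H]-       m/z = 182.9886
  [M+CH2O2-H]- m/z = 228.9941  (formate adduct)
  CF3-         m/z = 68.9958  (fragment anion)
  CF3COO-      m/z = 112.9856  (fragment anion)
hexazinone                   M        = 252.15863 Da
  [M+H]+       m/z = 253.1659
observed 182.9887 vs theoretical 182.9886: 0.43 ppm -> inside a 5 ppm match window
```

These are the numbers one checks a detected feature against: a
groundwater feature at m/z 182.9887 in negative mode is 0.43 ppm from
the theoretical deprotonated diol, well inside a 5 ppm accuracy
window, and its characteristic CF₃⁻ / CF₃COO⁻ fragments confirm the
fluorinated backbone.

End-to-end annotation (`python examples/match_queries.py`) builds a
50-compound stub library, corrupts every positive-mode 20 eV spectrum,
and matches the corrupted queries back:

```
50 queries, 50 reported annotations
true compound ranked first for 100% of queries
verdicts: {'accepted': 45, 'rejected': 5}
```

The CLI mirrors the same stages:

```
speclib simulate --compounds 100 --seed 1 --out run/
speclib prep     --input run/compounds.csv --out run/prep
speclib build    --compounds run/prep/msready_compounds.csv --msp run/lib.msp --db run/lib.db
speclib match    --library run/lib.msp --queries run/queries.msp --profile in_silico --out run/match
speclib validate --scores run/match/annotations.tsv --out run/val
```

## Scope

The fragmentation model itself is external: `speclib` defines the
predictor contract, parses batch output, and ships a deterministic
stub for testing — it does not reimplement a trained model. Feature
detection (peak picking, alignment, gap filling) is likewise upstream;
the package consumes already-extracted MS2 feature spectra (MSP/MGF).
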