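# Methods

This note documents the models, conventions and numerical choices
behind `speclib`, in the order the pipeline runs.

## Mass arithmetic

All masses derive from an embedded table of most-abundant-isotope
atomic masses (AME2020 values, ≥ 6 decimal places, 18 elements
covering organics plus common hetero/halogen/metal atoms), with
proton 1.00727646 Da and electron 0.00054858 Da. Adduct m/z values:
[M+H]⁺ = M + proton, [M−H]⁻ = M − proton; native ions [M]⁺/[M]⁻ only
correct for the electron mass, since their SMILES mass already
includes the charge carrier. The formate adduct [M+CH₂O₂−H]⁻
(= M + 46.00548 − proton) is supported because per-/polyfluorinated
diols are routinely detected as it in negative mode. At ppm-level
mass accuracy the electron mass (≈ 3 ppm at m/z 180) is not
negligible, which is why it is carried explicitly.

## MS-ready structure preparation

Order of operations: **desalt → neutralize → canonicalize**, the
standard MS-ready convention.

* *Desalting* splits the SMILES into distinct fragments and treats
  every carbon-free fragment as a counter-ion/solvent whenever a
  carbon-bearing fragment is present. One organic fragment remaining →
  it is the parent. Two or more distinct organic fragments → the
  record is a *residual salt* and is rejected (the canonical form
  would still contain a "."). A single inorganic species (water,
  ammonia) passes through and is caught by the mass filter. This rule
  keeps quaternary ammonium salts (counter-ion stripped, permanent
  charge kept) while refusing genuine multi-component mixtures, which
  a naive largest-fragment rule would silently truncate.
* *Neutralization* is rule-based (de)protonation via RDKit's
  `Uncharger`; permanent charges (quaternary N, etc.) survive. No
  pH model is applied.
* *Canonicalization* is RDKit canonical SMILES; idempotence
  (normalizing the output reproduces it) is tested.

Filter cascade, in fixed order so per-reason counts are reproducible:
mass < 40 Da, mass > 1000 Da, atom count > 200 (all atoms including
implicit hydrogens — the atom limit of batch fragmentation predictors
counts hydrogens), |net charge| ≥ 2 (single-charge predictors only).
A molecule can violate several bounds; it is reported under the first.
Note the >200-atom class is almost always also >1000 Da; molecules
that are over the atom limit but under the mass cap (C₆₇–C₇₁ alkanes
and the like) are the only ones reported as `too_many_atoms`.

Duplicates are merged by exact string comparison of canonical SMILES,
first occurrence wins, merged accessions kept as cross-references.
Stereoisomers have distinct canonical strings and are deliberately all
kept. Conservation — every input row becomes exactly one kept compound
or one rejection — is an invariant of the cascade, tested per class.

Records without structures can be resolved through an injectable
lookup (name → CAS → InChI → InChIKey); the test suite uses an offline
mapping resolver, and a live PubChem PUG REST client (stdlib urllib)
is provided for interactive use. Lookups never overwrite an existing
SMILES.

## Library formats

* **MSP**: MS-DIAL-compatible key spellings on write
  (`PRECURSORMZ`, `PRECURSORTYPE`, `IONMODE`, `COLLISIONENERGY`);
  common synonyms, any key case, and both `:`/`=` separators accepted
  on read. `NAME` carries the library accession (special characters in
  trade names break downstream parsers); the human name goes to
  `COMMENT`. A declared `Num Peaks` disagreeing with the actual
  peak-line count is repaired to the actual count with a logged
  warning — peak values are never altered. Floats are written with
  shortest-round-trip precision, making `read(write(L)) == L` exact.
* **SQLite** (mzVault-style, DDL in `speclib/db.py`): `CompoundTable`
  (one row per accession, with an embedded SDF structure block
  generated from SMILES) and `SpectrumTable` (one row per spectrum,
  foreign key to the compound), so the three collision-energy spectra
  of a compound share one compound entry, including across append
  calls. Peak arrays are space-separated text, not binary blobs: the
  file stays diffable and queryable and round-trips exactly.
* Predictor batch text (`#KEY=value` headers, `energy0/1/2` blocks)
  imports with blocks relabeled 10/20/40 eV by default; the relabeling
  map is configurable because vendor "corrected collision energy"
  conventions differ, and a separate relabeling pass can rewrite
  energies on an existing library.

## Matching

* *Candidate retrieval*: binary search on a precursor-sorted index,
  window 3 ppm (default), polarity-matched. Verified equivalent to a
  linear scan on random libraries.
* *Peak alignment*: greedy one-to-one pairing by smallest ppm
  deviation (relative to the reference peak m/z) within 5 ppm
  (default); ties broken by larger reference intensity, then lower
  index. All unmatched peaks from both sides are kept and paired with
  zero intensity. Greedy pairing is verified against exhaustive
  optimal assignment (maximize matches, then minimize total deviation)
  on 1,000 random pairs of ≤ 8-peak spectra; with centroided spectra
  (minimum peak spacing well above the tolerance window) the two
  cannot disagree outside exact ties.
* *Scores*: unweighted cosine on the aligned vectors (no intensity or
  m/z weighting, no renormalization — cosine is scale-invariant and no
  intensity floor is applied); explained intensity = matched fraction
  of one side's total intensity, **reference side by default**. The
  reference side is the deliberate choice: contaminant peaks occur in
  the measured query, so reference-side explained intensity is
  invariant under chimeric contamination while cosine degrades — that
  asymmetry is what lets the dual rule distinguish interference from
  genuine dissimilarity. The query side remains available via
  configuration. Matched-fragment count includes a matched precursor
  (declared precursor within tolerance) unless the precursor already
  appears among matched peaks, so it is never double-counted; the
  ambiguity of whether an unobserved-but-declared precursor should
  count is resolved in favour of counting it, since data-dependent
  acquisition guarantees the precursor was detected at MS1.
* *Per-compound aggregation*: each candidate compound is scored at
  every stored collision energy and the best-cosine energy is
  retained and reported, ties broken by explained intensity then lower
  energy. Best-of-three loses nothing and keeps the choice auditable.
* *Ranking*: descending cosine, ties by explained intensity then
  accession — deterministic and independent of library insertion order.
* *Decision profiles*: `experimental` = cosine ≥ 0.7 and explained
  intensity ≥ 0.9; `in_silico` = cosine ≥ 0.2 and explained intensity
  ≥ 0.7; both require ≥ 2 matched fragments, report nothing below
  cosine 0.1, and use 3/5 ppm tolerances. A match failing only the
  cosine floor is verdicted `candidate_for_curation` rather than
  rejected — the manual-review bucket where contaminated true
  positives land.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not chemistry:

* *Suspect tables*: clean survivors are drawn from parametric families
  of small organics (alcohols, acids, amides, aryl ethers,
  sulfonamides…, plus ~2% natively charged quaternary ammonium ions);
  planted defects per class: two-organic-component residual salts,
  sub-40 Da inorganics/fragments, perfluoroalkanes > 1000 Da,
  C₆₇–C₇₁ alkanes (> 200 atoms, < 1000 Da), bis-quaternary dications,
  and exact duplicates of earlier clean rows. Class fractions are
  caller-chosen; generation is deterministic per seed (sha256-derived
  PCG64 streams, no global state), and each duplicate is emitted after
  its original so first-occurrence-wins dedup matches the planted
  labels.
* *Reference spectra*: uniform peaks below the precursor (precursor
  ion included as the top peak), intensities on (0, 100], minimum peak
  spacing 0.05 Th as in centroided data. The spacing constraint also
  guarantees unambiguous alignment for the oracle-equivalence tests.
* *Corruption* defaults describe a well-behaved high-resolution run
  with visible matrix interference: m/z jitter σ = 1 ppm (5 ppm
  matching tolerance), multiplicative intensity noise CV = 0.2,
  dropout p = 0.1, 3 chimeric peaks at ≤ 0.5× base-peak intensity.
  Chimeric peaks are drawn outside ±2× tolerance of every true peak,
  so planted contamination never silently matches — which is what
  makes the robustness property (explained intensity exactly 1.0 under
  chimeric-only corruption) exact rather than approximate.
* *Stub predictor*: hash-seeded pseudo-fragments per (SMILES, adduct);
  three energies with fewer, lower-mass peaks at higher energy and the
  precursor ion surviving at 10/20 eV only. It reproduces the *shape*
  of collision-energy ramps so that library assembly, storage,
  best-energy selection and matching can be exercised; it contains no
  fragmentation chemistry, so passing tests say nothing about
  prediction quality on real spectra — only about the pipeline around
  the predictor.

Problem sizes in the test and acceptance suites (150–250-row tables,
200-compound end-to-end libraries, 1,000 oracle pairs, 100 × 3 round
trips) are chosen so the full suite runs in well under a minute while
every guarantee is exercised at a scale where failure modes (index
errors, tie-breaks, count drift) would surface.

## Known limitations

* Neutralization is rule-based; zwitterions and pH-dependent species
  are normalized to the RDKit-uncharged form, which may differ from a
  solution-phase dominant species.
* The residual-salt rule rejects genuine co-crystals/mixtures rather
  than selecting a parent; that is a curation decision, surfaced as a
  reasoned rejection rather than hidden.
* The SQLite schema is mzVault-*style*, self-documented in the DDL;
  bit-exact compatibility with any vendor tool is not claimed.
* Explained intensity has no community-standard definition; both sides
  are implemented and the reference-side default is a documented choice
  (see Matching).
* The stub predictor is a pipeline harness, not a model; real-library
  quality assessments require an external predictor behind the same
  contract.
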