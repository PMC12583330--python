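"""Seeded synthetic data: suspect tables, spectra, corruption, and the
deterministic stub predictor.

Every generator takes an explicit seed and is fully deterministic for
it (hash-derived PCG64 streams, no global state), so the whole pipeline
is testable without downloads and every planted defect is recoverable
class-by-class:

* compound tables plant residual salts, sub-40 Da and over-1000 Da
  masses, over-200-atom molecules, multiply charged species and exact
  duplicates at requested fractions, alongside clean survivors
  (including a sprinkle of natively charged single ions);
* reference spectra are centroided peak lists below the precursor with
  a minimum spacing of 0.05 Th;
* corruption emulates what degrades real query spectra relative to a
  library: ppm-scale mass jitter, multiplicative intensity noise,
  peak dropout, and chimeric contaminant peaks from co-isolated
  precursors;
* the stub predictor stands in for an external fragmentation model:
  hash-seeded pseudo-fragments per (SMILES, adduct), three collision
  energies, fewer and lower-mass peaks at higher energy.  It makes no
  claim to fragmentation chemistry — it exists so library assembly,
  storage and matching can be exercised end to end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem import CompoundRecord
from .masses import precursor_mz
from .spectra import Peak, Spectrum

__all__ = [
    "CorruptionConfig",
    "generate_compound_table",
    "generate_reference_spectrum",
    "corrupt_spectrum",
    "StubPredictor",
]


def _derive_seed(*parts) -> int:
    """Stable 31-bit seed from arbitrary parts (sha256, not Python's
    salted hash)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# compound tables with planted truth

# Clean survivors: parametric families guaranteed in-bounds and
# canonically distinct (varied chain length / decoration).
_KEEP_TEMPLATES = [
    lambda k: "C" * (k + 2) + "O",                        # alcohols
    lambda k: "C" * (k + 1) + "C(=O)O",                   # carboxylic acids
    lambda k: "C" * (k + 1) + "C(=O)N" + "C" * (k % 3 + 1),  # amides
    lambda k: "C" * (k + 1) + "c1ccccc1",                 # alkylbenzenes
    lambda k: "C" * (k + 1) + "Oc1ccc(Cl)cc1",            # chloroaryl ethers
    lambda k: "C" * (k + 1) + "N(C)C(=O)c1ccccc1",        # benzamides
    lambda k: "C" * (k + 1) + "OC(=O)c1ccc(N)cc1",        # aminobenzoates
    lambda k: "C" * (k + 1) + "S(=O)(=O)N",               # sulfonamides
    lambda k: "C" * (k + 1) + "Oc1ccc(C#N)cc1",           # cyanophenyl ethers
    lambda k: "C" * (k + 1) + "n1ccnc1",                  # imidazoles
]

# natively charged single ions that survive the cascade (quaternary
# ammonium cations, with a stripped halide counter-ion)
_NATIVE_ION_TEMPLATES = [
    lambda k: "C[N+](C)(C)" + "C" * (k + 2) + ".[Cl-]",
    lambda k: "C[N+](C)(C)" + "C" * (k + 2) + "O.[Br-]",
]

_SUB40 = ["C", "N", "O", "CO", "C=O", "CC", "C=C", "C#C", "NN", "CN", "OO", "C#N"]


def _over1000(k: int) -> str:
    # perfluoroalkanes: heavy but few atoms (C(20+k)F(42+2k), >1000 Da)
    return "FC(F)(F)" + "C(F)(F)" * (19 + k) + "F"


def _over200_atoms(k: int) -> str:
    # long alkanes: >200 atoms but still under 1000 Da (C67..C71)
    n = 67 + (k % 5)
    if k >= 5:  # methyl-branched isomers extend the family
        return "CC(C)" + "C" * (n - 4) + "C"
    return "C" * n


def _multicharged(k: int) -> str:
    # bis-quaternary ammonium dications (counter-ions stripped upstream)
    return "C[N+](C)(C)" + "C" * (k + 4) + "[N+](C)(C)C.[Cl-].[Cl-]"


def _residual_salt(k: int) -> str:
    # two distinct organic components survive counter-ion stripping
    return "C" * (k + 3) + "O." + "C" * (k + 2) + "N"


def generate_compound_table(
    n: int,
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    native_ion_fraction: float = 0.02,
) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Generate a suspect table of ``n`` records with planted defects.

    ``fractions`` maps defect class (``salt``, ``sub40``, ``over1000``,
    ``over200atoms``, ``multicharged``, ``duplicate``) to the fraction
    of records planted with it; they must sum to <= 1.  Returns the
    records (shuffled deterministically) and a truth map
    ``source_id -> class`` where clean survivors are labelled ``keep``.
    Duplicates are planted as re-listings of an earlier clean record.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    fractions = dict(fractions or {})
    known = {"salt", "sub40", "over1000", "over200atoms", "multicharged", "duplicate"}
    unknown = set(fractions) - known
    if unknown:
        raise ValueError(f"unknown defect classes: {sorted(unknown)}")
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("defect fractions must sum to <= 1")
    rng = np.random.default_rng(_derive_seed("compound_table", seed))

    counts = {cls: int(round(n * f)) for cls, f in fractions.items()}
    n_keep = n - sum(counts.values())
    if n_keep < counts.get("duplicate", 0) > 0 and n_keep < 1:
        raise ValueError("need at least one clean record to duplicate")

    entries: list[tuple[str, str]] = []  # (class, smiles)
    keep_pool: list[str] = []
    ki = 0
    n_native = min(int(round(n_keep * native_ion_fraction)), n_keep)
    while len(keep_pool) < n_keep:
        if len(keep_pool) < n_native:
            template = _NATIVE_ION_TEMPLATES[ki % len(_NATIVE_ION_TEMPLATES)]
        else:
            template = _KEEP_TEMPLATES[ki % len(_KEEP_TEMPLATES)]
        keep_pool.append(template(ki // len(_KEEP_TEMPLATES) + ki % 7))
        ki += 1
    keep_pool = list(dict.fromkeys(keep_pool))  # drop accidental repeats
    while len(keep_pool) < n_keep:  # refill with longer chains if needed
        keep_pool.append("C" * (len(keep_pool) + 20) + "C(=O)OC")
    entries.extend(("keep", s) for s in keep_pool[:n_keep])

    for i in range(counts.get("salt", 0)):
        entries.append(("salt", _residual_salt(i)))
    for i in range(counts.get("sub40", 0)):
        entries.append(("sub40", _SUB40[i % len(_SUB40)]))
    for i in range(counts.get("over1000", 0)):
        entries.append(("over1000", _over1000(i)))
    for i in range(counts.get("over200atoms", 0)):
        entries.append(("over200atoms", _over200_atoms(i)))
    for i in range(counts.get("multicharged", 0)):
        entries.append(("multicharged", _multicharged(i)))
    n_dup = counts.get("duplicate", 0)
    if n_dup and not keep_pool:
        raise ValueError("cannot plant duplicates without clean records")
    for i in range(n_dup):
        entries.append(("duplicate", keep_pool[i % min(n_keep, len(keep_pool))]))

    # shuffle, but keep each duplicate after its original so
    # first-occurrence-wins dedup matches the planted labels
    order = rng.permutation(len(entries))
    originals = {s: None for cls, s in entries if cls == "keep"}
    shuffled: list[tuple[str, str]] = []
    deferred: list[tuple[str, str]] = []
    for idx in order:
        cls, smiles = entries[idx]
        if cls == "duplicate" and originals.get(smiles, "absent") is None:
            deferred.append((cls, smiles))
            continue
        if cls == "keep":
            originals[smiles] = True
        shuffled.append((cls, smiles))
        if cls == "keep":
            shuffled.extend(d for d in deferred if d[1] == smiles)
            deferred = [d for d in deferred if d[1] != smiles]
    shuffled.extend(deferred)

    records: list[CompoundRecord] = []
    truth: dict[str, str] = {}
    for i, (cls, smiles) in enumerate(shuffled):
        source_id = f"NS{seed % 100:02d}{i:06d}"
        records.append(
            CompoundRecord(source_id=source_id, name=f"synthetic compound {i}", smiles_raw=smiles)
        )
        truth[source_id] = cls
    return records, truth


# ---------------------------------------------------------------------------
# spectra

MIN_PEAK_SPACING = 0.05  # Th; centroided spectra do not carry closer peaks


def generate_reference_spectrum(
    precursor: float,
    n_peaks: int,
    seed: int = 0,
    compound_id: str = "synthetic",
    polarity: str = "positive",
    collision_energy: float = 20.0,
) -> Spectrum:
    """A centroided peak list for one precursor: ``n_peaks`` peaks at or
    below the precursor m/z (the precursor ion itself is always
    included as the top-mass peak), intensities on (0, 100], minimum
    peak spacing 0.05 Th."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if precursor <= 40:
        raise ValueError("precursor m/z must exceed 40")
    rng = np.random.default_rng(_derive_seed("ref_spectrum", seed, compound_id))
    mzs = [precursor]
    lo = max(20.0, precursor * 0.1)
    attempts = 0
    while len(mzs) < n_peaks and attempts < 10000:
        candidate = float(rng.uniform(lo, precursor - 1.0))
        if all(abs(candidate - m) >= MIN_PEAK_SPACING for m in mzs):
            mzs.append(candidate)
        attempts += 1
    intensities = rng.uniform(5.0, 100.0, size=len(mzs))
    peaks = [Peak(m, float(i)) for m, i in zip(mzs, intensities)]
    return Spectrum(
        compound_id=compound_id,
        peaks=peaks,
        precursor_mz=precursor,
        polarity=polarity,
        collision_energy=collision_energy,
        provenance="experimental",
    )


@dataclass(frozen=True)
class CorruptionConfig:
    """What degrades a measured query spectrum relative to its library
    reference.  Defaults describe a well-behaved high-resolution run
    with visible matrix interference: 1 ppm mass jitter (well inside a
    5 ppm matching tolerance), 20% multiplicative intensity noise, 10%
    peak dropout, and 3 chimeric contaminant peaks at up to half the
    base-peak intensity."""

    ppm_jitter_sd: float = 1.0
    intensity_noise_cv: float = 0.2
    dropout_p: float = 0.1
    n_chimeric: int = 3
    chimeric_intensity_scale: float = 0.5
    fragment_tol_ppm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout_p must be a probability")
        if min(self.ppm_jitter_sd, self.intensity_noise_cv, self.chimeric_intensity_scale) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


def corrupt_spectrum(reference: Spectrum, config: CorruptionConfig) -> Spectrum:
    """Degrade a reference spectrum into a realistic query: ppm-scale
    normal m/z jitter, multiplicative intensity noise, Bernoulli peak
    dropout (never below one surviving peak), and injected chimeric
    peaks.

    Chimeric peaks are drawn uniformly over the spectrum's m/z range
    but outside +/- 2x the fragment tolerance around every true peak,
    so planted contamination can never silently match the reference.
    """
    rng = np.random.default_rng(_derive_seed("corrupt", config.seed, reference.compound_id))
    mz = reference.mz.copy()
    intensity = reference.intensity.copy()

    if config.ppm_jitter_sd > 0:
        mz = mz * (1.0 + rng.normal(0.0, config.ppm_jitter_sd * 1e-6, size=mz.size))
    if config.intensity_noise_cv > 0:
        factors = np.clip(
            1.0 + rng.normal(0.0, config.intensity_noise_cv, size=intensity.size), 0.05, None
        )
        intensity = intensity * factors
    keep = rng.random(mz.size) >= config.dropout_p
    if not keep.any():
        keep[int(np.argmax(intensity))] = True
    mz, intensity = mz[keep], intensity[keep]

    peaks = [Peak(float(m), float(i)) for m, i in zip(mz, intensity)]
    if config.n_chimeric > 0:
        lo = max(20.0, float(reference.mz.min()) - 10.0)
        hi = reference.precursor_mz + 0.5
        base = float(intensity.max()) if intensity.size else 100.0
        exclusion = 2.0 * config.fragment_tol_ppm * 1e-6
        true_mz = reference.mz
        added = 0
        attempts = 0
        while added < config.n_chimeric and attempts < 1000:
            attempts += 1
            candidate = float(rng.uniform(lo, hi))
            if np.any(np.abs(candidate - true_mz) <= true_mz * exclusion):
                continue
            peaks.append(
                Peak(candidate,
                     float(rng.uniform(0.2, 1.0) * config.chimeric_intensity_scale * base))
            )
            added += 1
    return reference.copy(peaks=peaks, provenance="experimental")


# ---------------------------------------------------------------------------
# stub predictor

class StubPredictor:
    """Deterministic stand-in for an external fragmentation model.

    Fragments are pseudo-random but fully determined by a sha256 hash
    of (SMILES, adduct): a base pool of fragment m/z values below the
    precursor, emitted as three collision-energy spectra in which
    higher energy keeps fewer and lower-mass fragments (the precursor
    ion survives at 10 and 20 eV, not at 40 eV) — the qualitative shape
    of collision-energy ramps, with no fragmentation chemistry behind it.
    """

    supported_adducts = ("[M+H]+", "[M-H]-", "[M]+", "[M]-")
    energies = (10.0, 20.0, 40.0)

    def __init__(self, n_fragments: int = 10, seed: int = 0):
        self.n_fragments = n_fragments
        self.seed = seed

    def _neutral_mass(self, smiles: str) -> float:
        from rdkit import Chem
        from rdkit.Chem.Descriptors import ExactMolWt

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"stub predictor cannot parse SMILES {smiles!r}")
        return ExactMolWt(mol)

    def predict(self, smiles: str, adduct: str) -> dict[float, list[Peak]]:
        if adduct not in self.supported_adducts:
            raise ValueError(
                f"unsupported adduct {adduct!r}; stub supports {self.supported_adducts}"
            )
        mass = self._neutral_mass(smiles)
        if adduct in ("[M]+", "[M]-"):
            # native ions: SMILES mass already includes the charge carrier
            pmz = precursor_mz(mass, adduct)
        else:
            pmz = precursor_mz(mass, adduct)
        rng = np.random.default_rng(_derive_seed("stub", self.seed, smiles, adduct))
        pool: list[float] = []
        lo = max(20.0, pmz * 0.15)
        while len(pool) < self.n_fragments:
            candidate = float(rng.uniform(lo, pmz - 2.0))
            if all(abs(candidate - m) >= MIN_PEAK_SPACING for m in pool):
                pool.append(candidate)
        pool.sort()
        out: dict[float, list[Peak]] = {}
        for energy, drop_high, keep_precursor in (
            (10.0, 0, True), (20.0, 2, True), (40.0, 4, False),
        ):
            frag_mz = pool[: len(pool) - drop_high]
            mzs = list(frag_mz) + ([pmz] if keep_precursor else [])
            intensities = rng.uniform(5.0, 100.0, size=len(mzs))
            out[energy] = [Peak(m, float(i)) for m, i in zip(mzs, intensities)]
        return out
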