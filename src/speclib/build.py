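"""Library assembly around a pluggable spectrum predictor.

The fragmentation model itself is external (e.g. a CFM-ID container);
this module defines the contract a predictor must satisfy, drives batch
prediction over MS-ready compounds, parses predictor batch output text,
and completes MSP metadata from the compound table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from rdkit import Chem

from .chem import MsReadyCompound, classify_ion_species
from .masses import monoisotopic_mass, parse_formula, ppm_difference, precursor_mz
from .spectra import Peak, Spectrum, SpectralLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumPredictor",
    "ExternalProcessPredictor",
    "predict_spectra",
    "PredictionReport",
    "import_predictor_output",
    "ImportResult",
    "complete_metadata",
    "relabel_energies",
]

#: consistency tolerance between declared precursor m/z and the value
#: recomputed from formula + adduct
PRECURSOR_CONSISTENCY_PPM = 10.0


class SpectrumPredictor(Protocol):
    """Contract: (SMILES, adduct) -> collision-energy-labelled peak lists."""

    supported_adducts: tuple[str, ...]

    def predict(self, smiles: str, adduct: str) -> dict[float, list[Peak]]:
        """Return {collision_energy_eV: peaks}; raise ValueError for an
        unsupported adduct."""
        ...


class ExternalProcessPredictor:
    """Adapter that shells out to an external predictor command (e.g. a
    CFM-ID container invocation) producing batch output text, which is
    then parsed with :func:`import_predictor_output`.

    The command receives ``{smiles}`` and ``{adduct}`` placeholders.
    """

    supported_adducts = ("[M+H]+", "[M-H]-", "[M]+", "[M]-")

    def __init__(self, command_template: str, dialect: str = "cfm-id"):
        self.command_template = command_template
        self.dialect = dialect

    def predict(self, smiles: str, adduct: str) -> dict[float, list[Peak]]:
        import io
        import subprocess

        if adduct not in self.supported_adducts:
            raise ValueError(f"unsupported adduct {adduct!r}")
        cmd = self.command_template.format(smiles=smiles, adduct=adduct)
        out = subprocess.run(
            cmd, shell=True, capture_output=True, text=True, check=True
        ).stdout
        result = import_predictor_output(io.StringIO(out), dialect=self.dialect)
        return {
            s.collision_energy: list(s.peaks) for s in result.library
        }


@dataclass
class PredictionReport:
    n_compounds: int = 0
    n_spectra: int = 0
    failures: dict[str, str] = field(default_factory=dict)


def predict_spectra(
    compounds: Sequence[MsReadyCompound],
    predictor: SpectrumPredictor,
    adducts: Sequence[str] | None = None,
) -> tuple[SpectralLibrary, PredictionReport]:
    """Predict spectra for every compound at each of its ion species
    (neutrals in both polarities, native ions in their own).

    ``adducts`` restricts prediction to an explicit subset and must be
    supported by the predictor.  A predictor failure on one compound is
    reported and skipped; the run continues.
    """
    if adducts is not None:
        for a in adducts:
            if a not in predictor.supported_adducts:
                raise ValueError(f"adduct {a!r} not supported by predictor")
    library = SpectralLibrary()
    report = PredictionReport()
    for compound in compounds:
        report.n_compounds += 1
        try:
            species = classify_ion_species(compound)
            if adducts is not None:
                species = [s for s in species if s.adduct_label in adducts]
            for ion in species:
                for energy, peaks in sorted(predictor.predict(
                    compound.smiles_canonical, ion.adduct_label
                ).items()):
                    library.append(
                        Spectrum(
                            compound_id=compound.source_id,
                            peaks=peaks,
                            precursor_mz=ion.mz,
                            adduct_label=ion.adduct_label,
                            polarity=ion.polarity,
                            collision_energy=energy,
                            provenance="predicted",
                            formula=compound.formula_string,
                            smiles=compound.smiles_canonical,
                            name=compound.name,
                        )
                    )
                    report.n_spectra += 1
        except Exception as exc:
            report.failures[compound.source_id] = str(exc)
            logger.warning("prediction failed for %s: %s", compound.source_id, exc)
    return library, report


# ---------------------------------------------------------------------------
# predictor batch-output import

@dataclass
class ImportResult:
    library: SpectralLibrary
    n_skipped: int = 0


# CFM-ID batch output labels its three blocks energy0/energy1/energy2
CFM_ENERGY_LABELS = {"energy0": 10.0, "energy1": 20.0, "energy2": 40.0}


def import_predictor_output(
    source, dialect: str = "cfm-id",
    energy_map: Mapping[str, float] | None = None,
) -> ImportResult:
    """Parse predictor batch output text into a library of
    provenance=predicted spectra.

    The ``cfm-id`` dialect is ``#KEY=value`` header lines (at least
    ``#ID=`` and usually ``#SMILES=``) followed by ``energy0/1/2``
    blocks of ``m/z intensity`` lines; compounds are separated by blank
    lines.  ``energy_map`` relabels block names to corrected collision
    energies.  Malformed blocks (peaks before any energy header) are
    skipped and counted.
    """
    if dialect != "cfm-id":
        raise ValueError(f"unknown predictor dialect {dialect!r}")
    energies = dict(energy_map or CFM_ENERGY_LABELS)
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    library = SpectralLibrary()
    n_skipped = 0
    meta: dict[str, str] = {}
    blocks: dict[float, list[Peak]] = {}
    current_energy: float | None = None
    orphan_peaks = False

    def flush() -> None:
        nonlocal meta, blocks, current_energy, orphan_peaks, n_skipped
        if orphan_peaks:
            n_skipped += 1
            logger.warning("predictor block without energy header skipped (ID=%s)",
                           meta.get("ID", "?"))
        cid = meta.get("ID", "")
        for energy in sorted(blocks):
            peaks = blocks[energy]
            if not cid or not peaks:
                continue
            library.append(
                Spectrum(
                    compound_id=cid,
                    peaks=peaks,
                    precursor_mz=float(meta.get("PMASS", 0) or 0),
                    adduct_label=meta.get("ADDUCT", ""),
                    collision_energy=energy,
                    provenance="predicted",
                    smiles=meta.get("SMILES", ""),
                )
            )
        meta, blocks, current_energy, orphan_peaks = {}, {}, None, False

    for raw in lines:
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip().upper()] = value.strip()
            continue
        label = line.lower()
        if label in energies:
            current_energy = energies[label]
            blocks.setdefault(current_energy, [])
            continue
        parts = line.split()
        if len(parts) >= 2:
            try:
                peak = Peak(float(parts[0]), float(parts[1]))
            except ValueError:
                continue
            if current_energy is None:
                orphan_peaks = True
            else:
                blocks[current_energy].append(peak)
    flush()
    return ImportResult(library, n_skipped)


# ---------------------------------------------------------------------------
# metadata completion

def _polarity_of(adduct: str) -> str:
    if adduct.endswith("+"):
        return "positive"
    if adduct.endswith("-"):
        return "negative"
    return ""


def complete_metadata(
    library: SpectralLibrary, compounds: Iterable[MsReadyCompound]
) -> SpectralLibrary:
    """Fill missing spectrum metadata (formula, SMILES, InChI, InChIKey,
    polarity, precursor m/z) from the MS-ready compound table, joined on
    compound_id.  Existing values are never overwritten; a declared
    precursor that disagrees with formula+adduct by more than 10 ppm
    draws a conflict warning.  Unmatched compound_ids are reported and
    left as they are."""
    by_id = {c.source_id: c for c in compounds}
    out = SpectralLibrary()
    for s in library:
        s = s.copy()
        c = by_id.get(s.compound_id)
        if c is None:
            logger.warning("no compound table entry for %s; left incomplete", s.compound_id)
            out.append(s)
            continue
        if not s.formula:
            s.formula = c.formula_string
        if not s.smiles:
            s.smiles = c.smiles_canonical
        if not s.name:
            s.name = c.name
        if (not s.inchi or not s.inchikey) and s.smiles:
            mol = Chem.MolFromSmiles(s.smiles)
            if mol is not None:
                if not s.inchi:
                    s.inchi = Chem.MolToInchi(mol)
                if not s.inchikey:
                    s.inchikey = Chem.MolToInchiKey(mol)
        if not s.polarity and s.adduct_label:
            s.polarity = _polarity_of(s.adduct_label)
        if s.adduct_label and s.formula:
            try:
                expected = precursor_mz(
                    monoisotopic_mass(parse_formula(s.formula)), s.adduct_label
                )
            except ValueError:
                expected = None
            if expected is not None:
                if s.precursor_mz <= 0:
                    s.precursor_mz = expected
                elif abs(ppm_difference(s.precursor_mz, expected)) > PRECURSOR_CONSISTENCY_PPM:
                    logger.warning(
                        "%s: declared precursor %.5f disagrees with %s of %s (%.5f) by >%g ppm",
                        s.compound_id, s.precursor_mz, s.adduct_label, s.formula,
                        expected, PRECURSOR_CONSISTENCY_PPM,
                    )
        out.append(s)
    return out


def relabel_energies(
    library: SpectralLibrary, mapping: Mapping[float, float]
) -> SpectralLibrary:
    """Apply a corrected-collision-energy relabeling map (e.g. nominal
    eV -> instrument NCE); energies absent from the map pass through."""
    out = SpectralLibrary()
    for s in library:
        out.append(s.copy(collision_energy=mapping.get(s.collision_energy, s.collision_energy)))
    return out
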