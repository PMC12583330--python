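"""NIST MSP reading/writing and MGF query import.

The MSP dialect written here uses the MS-DIAL-compatible key spellings
(``PRECURSORMZ``, ``PRECURSORTYPE``, ``IONMODE``, ``COLLISIONENERGY``)
with ``NAME`` carrying the library compound ID (special characters in
trade names break downstream tools; the human-readable name goes to
``COMMENT``).  The reader is deliberately tolerant: keys are matched
case-insensitively with common synonyms, ``:`` and ``=`` separators are
both accepted, and a declared ``Num Peaks`` that disagrees with the
actual peak-line count is repaired to the actual count with a logged
warning — peak values are never altered.

MGF peak lists (the usual export for detected MS2 features) are read
through :mod:`pyteomics.mgf`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TextIO

from .spectra import Peak, Spectrum, SpectralLibrary

logger = logging.getLogger(__name__)

__all__ = ["read_msp", "write_msp", "read_mgf", "read_queries"]

# normalized (upper, no space/_/-) synonym -> canonical field
_KEY_SYNONYMS = {
    "NAME": "name",
    "PRECURSORMZ": "precursor_mz",
    "PRECURSORM/Z": "precursor_mz",
    "PEPMASS": "precursor_mz",
    "PRECURSORTYPE": "adduct_label",
    "ADDUCT": "adduct_label",
    "ADDUCTTYPE": "adduct_label",
    "IONMODE": "polarity",
    "IONIZATIONMODE": "polarity",
    "POLARITY": "polarity",
    "COLLISIONENERGY": "collision_energy",
    "CE": "collision_energy",
    "FORMULA": "formula",
    "MOLECULARFORMULA": "formula",
    "SMILES": "smiles",
    "INCHIKEY": "inchikey",
    "INCHI": "inchi",
    "COMMENT": "comment",
    "COMMENTS": "comment",
    "SYNON": "comment",
    "NUMPEAKS": "num_peaks",
    "PROVENANCE": "provenance",
}


def _normalize_key(key: str) -> str | None:
    return _KEY_SYNONYMS.get(key.strip().upper().replace(" ", "").replace("_", "").replace("-", ""))


def _normalize_polarity(value: str) -> str:
    v = value.strip().lower()
    if v in ("positive", "pos", "p", "+", "1"):
        return "positive"
    if v in ("negative", "neg", "n", "-", "-1"):
        return "negative"
    return v


def _parse_energy(value: str) -> float:
    # accept "20", "20.0", "20 eV", "20eV"
    token = value.strip().lower().removesuffix("ev").strip()
    try:
        return float(token)
    except ValueError:
        return 0.0


def _finish_entry(fields: dict, peaks: list[Peak], origin: str) -> Spectrum | None:
    name = fields.get("name", "")
    if not name:
        logger.warning("%s: entry without NAME skipped", origin)
        return None
    if not peaks:
        logger.warning("%s: entry %r with empty peak block skipped", origin, name)
        return None
    declared = fields.get("num_peaks")
    if declared is not None and declared != len(peaks):
        logger.warning(
            "%s: entry %r declares %d peaks but has %d; repaired to actual count",
            origin, name, declared, len(peaks),
        )
    return Spectrum(
        compound_id=name,
        peaks=peaks,
        precursor_mz=fields.get("precursor_mz", 0.0),
        adduct_label=fields.get("adduct_label", ""),
        polarity=fields.get("polarity", ""),
        collision_energy=fields.get("collision_energy", 0.0),
        provenance=fields.get("provenance", "experimental"),
        formula=fields.get("formula", ""),
        smiles=fields.get("smiles", ""),
        inchi=fields.get("inchi", ""),
        inchikey=fields.get("inchikey", ""),
        name=fields.get("comment", ""),
    )


def read_msp(path: str | Path) -> SpectralLibrary:
    """Parse an MSP spectral library file into a :class:`SpectralLibrary`.

    Entries missing a NAME or with an empty peak block are skipped with
    a warning; declared-vs-actual peak-count mismatches are repaired.
    """
    path = Path(path)
    library = SpectralLibrary()
    fields: dict = {}
    peaks: list[Peak] = []
    in_entry = False

    def flush() -> None:
        nonlocal fields, peaks, in_entry
        if in_entry:
            spectrum = _finish_entry(fields, peaks, str(path))
            if spectrum is not None:
                library.append(spectrum)
        fields, peaks, in_entry = {}, [], False

    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            # peak line: starts with a digit and has no key separator before whitespace
            first = line.replace(";", " ").split(None, 1)[0]
            is_peak = False
            if first[0].isdigit():
                try:
                    float(first)
                    is_peak = True
                except ValueError:
                    is_peak = False
            if is_peak:
                parts = line.replace(";", " ").split()
                if len(parts) >= 2:
                    try:
                        peaks.append(Peak(float(parts[0]), float(parts[1])))
                        in_entry = True
                        continue
                    except ValueError:
                        pass
            for sep in (":", "="):
                if sep in line:
                    key, _, value = line.partition(sep)
                    field = _normalize_key(key)
                    value = value.strip()
                    if field is None:
                        break
                    in_entry = True
                    if field == "num_peaks":
                        try:
                            fields[field] = int(float(value))
                        except ValueError:
                            pass
                    elif field == "precursor_mz":
                        try:
                            fields[field] = float(value.split()[0])
                        except (ValueError, IndexError):
                            pass
                    elif field == "collision_energy":
                        fields[field] = _parse_energy(value)
                    elif field == "polarity":
                        fields[field] = _normalize_polarity(value)
                    else:
                        fields.setdefault(field, value)
                    break
    flush()
    return library


def _write_entry(spectrum: Spectrum, fh: TextIO) -> None:
    fh.write(f"NAME: {spectrum.compound_id}\n")
    fh.write(f"PRECURSORMZ: {spectrum.precursor_mz!r}\n")
    if spectrum.adduct_label:
        fh.write(f"PRECURSORTYPE: {spectrum.adduct_label}\n")
    if spectrum.polarity:
        fh.write(f"IONMODE: {spectrum.polarity.capitalize()}\n")
    if spectrum.collision_energy:
        ce = spectrum.collision_energy
        fh.write(f"COLLISIONENERGY: {int(ce) if ce == int(ce) else ce}\n")
    if spectrum.formula:
        fh.write(f"FORMULA: {spectrum.formula}\n")
    if spectrum.smiles:
        fh.write(f"SMILES: {spectrum.smiles}\n")
    if spectrum.inchi:
        fh.write(f"INCHI: {spectrum.inchi}\n")
    if spectrum.inchikey:
        fh.write(f"INCHIKEY: {spectrum.inchikey}\n")
    if spectrum.provenance:
        fh.write(f"PROVENANCE: {spectrum.provenance}\n")
    if spectrum.name:
        fh.write(f"COMMENT: {spectrum.name}\n")
    fh.write(f"Num Peaks: {len(spectrum.peaks)}\n")
    for p in spectrum.peaks:  # Spectrum keeps peaks sorted ascending
        fh.write(f"{p.mz!r} {p.intensity!r}\n")
    fh.write("\n")


def write_msp(library: SpectralLibrary, path: str | Path) -> Path:
    """Write one MSP block per spectrum.  ``Num Peaks`` always equals
    the emitted peak-line count; floats are written with full
    round-trip precision."""
    path = Path(path)
    for i, s in enumerate(library):
        if not s.compound_id:
            raise ValueError(f"entry {i} has no compound_id")
        if s.precursor_mz <= 0:
            raise ValueError(f"entry {i} ({s.compound_id}) has no precursor m/z")
        if not s.peaks:
            raise ValueError(f"entry {i} ({s.compound_id}) has no peaks")
        if not s.polarity:
            raise ValueError(f"entry {i} ({s.compound_id}) has no polarity")
    with path.open("w") as fh:
        for s in library:
            _write_entry(s, fh)
    return path


def read_mgf(path: str | Path) -> SpectralLibrary:
    """Read MGF query peak lists (pyteomics) into spectra.  TITLE maps
    to compound_id, PEPMASS to precursor m/z, and polarity is taken
    from the charge sign or an explicit ION/IONMODE parameter."""
    from pyteomics import mgf

    library = SpectralLibrary()
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            polarity = ""
            if "ionmode" in params:
                polarity = _normalize_polarity(str(params["ionmode"]))
            elif "charge" in params and params["charge"]:
                polarity = "positive" if int(params["charge"][0]) > 0 else "negative"
            mzs = entry["m/z array"]
            intensities = entry["intensity array"]
            peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, intensities)]
            if not peaks:
                logger.warning("%s: empty MGF block %r skipped", path, params.get("title"))
                continue
            library.append(
                Spectrum(
                    compound_id=str(params.get("title", f"query_{len(library)}")),
                    peaks=peaks,
                    precursor_mz=float(params["pepmass"][0]),
                    polarity=polarity,
                )
            )
    return library


def read_queries(path: str | Path) -> SpectralLibrary:
    """Read query spectra from MSP or MGF, dispatching on extension."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        return read_mgf(path)
    return read_msp(path)
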