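"""SQLite spectral database (mzVault-style schema).

One row per compound and one row per spectrum, so the three predicted
collision energies of a compound share a single compound entry instead
of appearing as three independent library entries.  Peak arrays are
stored as space-separated text columns (full float precision) rather
than opaque blobs, which keeps the file diffable and queryable from any
SQLite client.  An SDF structure block is embedded per compound when a
SMILES is available.  The DDL below is the schema contract.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

from .spectra import Peak, Spectrum, SpectralLibrary

__all__ = ["build_spectral_db", "read_spectral_db", "SCHEMA_DDL"]

SCHEMA_DDL = """
CREATE TABLE IF NOT EXISTS CompoundTable (
    CompoundId INTEGER PRIMARY KEY,
    CompoundName TEXT NOT NULL UNIQUE,   -- library ID (e.g. SusDat accession)
    HumanName TEXT,
    Formula TEXT,
    SMILES TEXT,
    InChI TEXT,
    InChIKey TEXT,
    Structure TEXT                        -- SDF mol block, may be empty
);
CREATE TABLE IF NOT EXISTS SpectrumTable (
    SpectrumId INTEGER PRIMARY KEY,
    CompoundId INTEGER NOT NULL REFERENCES CompoundTable(CompoundId),
    CollisionEnergy REAL,
    PrecursorMass REAL NOT NULL,
    Adduct TEXT,
    Polarity TEXT,
    Provenance TEXT,
    PeakMZ TEXT NOT NULL,                 -- space-separated m/z values
    PeakIntensity TEXT NOT NULL           -- space-separated intensities
);
CREATE INDEX IF NOT EXISTS idx_spectrum_precursor ON SpectrumTable(PrecursorMass);
CREATE INDEX IF NOT EXISTS idx_spectrum_compound ON SpectrumTable(CompoundId);
"""


def _sdf_block(smiles: str) -> str:
    if not smiles:
        return ""
    try:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return ""
        return Chem.MolToMolBlock(mol) + "$$$$\n"
    except Exception:
        return ""


def build_spectral_db(
    library: SpectralLibrary,
    path: str | Path,
    append: bool = False,
    with_structures: bool = True,
) -> Path:
    """Write (or extend) a spectral database.  Spectra sharing a
    compound_id collapse onto one compound row — including across calls
    when ``append`` is true — with metadata taken from the first
    spectrum that provides it."""
    path = Path(path)
    if path.exists() and not append:
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(SCHEMA_DDL)
        compound_ids: dict[str, int] = {
            name: cid
            for cid, name in con.execute("SELECT CompoundId, CompoundName FROM CompoundTable")
        }
        for s in library:
            cid = compound_ids.get(s.compound_id)
            if cid is None:
                cur = con.execute(
                    "INSERT INTO CompoundTable "
                    "(CompoundName, HumanName, Formula, SMILES, InChI, InChIKey, Structure) "
                    "VALUES (?,?,?,?,?,?,?)",
                    (s.compound_id, s.name, s.formula, s.smiles, s.inchi, s.inchikey,
                     _sdf_block(s.smiles) if with_structures else ""),
                )
                cid = cur.lastrowid
                compound_ids[s.compound_id] = cid
            con.execute(
                "INSERT INTO SpectrumTable "
                "(CompoundId, CollisionEnergy, PrecursorMass, Adduct, Polarity, Provenance, "
                "PeakMZ, PeakIntensity) VALUES (?,?,?,?,?,?,?,?)",
                (cid, s.collision_energy, s.precursor_mz, s.adduct_label, s.polarity,
                 s.provenance,
                 " ".join(repr(p.mz) for p in s.peaks),
                 " ".join(repr(p.intensity) for p in s.peaks)),
            )
        con.commit()
    finally:
        con.close()
    return path


def read_spectral_db(path: str | Path) -> SpectralLibrary:
    """Load a spectral database back into a :class:`SpectralLibrary`."""
    con = sqlite3.connect(path)
    library = SpectralLibrary()
    try:
        rows = con.execute(
            "SELECT c.CompoundName, c.HumanName, c.Formula, c.SMILES, c.InChI, c.InChIKey, "
            "s.CollisionEnergy, s.PrecursorMass, s.Adduct, s.Polarity, s.Provenance, "
            "s.PeakMZ, s.PeakIntensity "
            "FROM SpectrumTable s JOIN CompoundTable c USING (CompoundId) "
            "ORDER BY s.SpectrumId"
        )
        for (name, human, formula, smiles, inchi, inchikey, energy, precursor,
             adduct, polarity, provenance, mz_text, int_text) in rows:
            mzs = [float(x) for x in mz_text.split()]
            intensities = [float(x) for x in int_text.split()]
            library.append(
                Spectrum(
                    compound_id=name,
                    peaks=[Peak(m, i) for m, i in zip(mzs, intensities)],
                    precursor_mz=precursor,
                    adduct_label=adduct or "",
                    polarity=polarity or "",
                    collision_energy=energy or 0.0,
                    provenance=provenance or "experimental",
                    formula=formula or "",
                    smiles=smiles or "",
                    inchi=inchi or "",
                    inchikey=inchikey or "",
                    name=human or "",
                )
            )
    finally:
        con.close()
    return library
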