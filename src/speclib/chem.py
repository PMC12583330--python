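"""MS-ready compound preparation.

Turns raw suspect-list entries (SMILES plus assorted identifiers) into
MS-ready structures: desalted, charge-neutralized where chemically
possible, canonicalized, with elemental composition, monoisotopic mass,
net charge and atom count attached.  A filter cascade then removes
records a single-charged small-molecule fragmentation predictor cannot
handle, duplicates are merged on canonical SMILES, and each survivor is
assigned the ion species it will be predicted for.

Every input record ends up in exactly one of two buckets — an
:class:`MsReadyCompound` or a :class:`RejectionRecord` — so counts are
conserved and each rejection carries a machine-readable reason.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .masses import monoisotopic_mass, precursor_mz, formula_to_string

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "MsReadyCompound",
    "RejectionRecord",
    "IonSpecies",
    "CleanupResult",
    "normalize_structure",
    "apply_filters",
    "deduplicate",
    "classify_ion_species",
    "resolve_missing_structures",
    "clean_table",
    "read_compound_table",
    "write_cleanup_outputs",
]

REJECTION_REASONS = (
    "no_structure",
    "unparsable",
    "residual_salt",
    "mass_below_min",
    "mass_above_max",
    "too_many_atoms",
    "multiply_charged",
    "duplicate",
)

MASS_MIN_DA = 40.0
MASS_MAX_DA = 1000.0
ATOM_MAX = 200


@dataclass
class CompoundRecord:
    """One raw suspect-list entry."""

    source_id: str
    name: str = ""
    smiles_raw: str = ""
    inchi: str = ""
    inchikey: str = ""
    cas: str = ""


@dataclass
class MsReadyCompound:
    """A desalted, neutralized, canonical structure ready for mass and
    spectrum computation."""

    source_id: str
    smiles_canonical: str
    formula: dict[str, int]
    monoisotopic_mass: float
    net_charge: int
    atom_count: int
    name: str = ""
    cross_refs: list[str] = field(default_factory=list)

    @property
    def ion_class(self) -> str:
        return {0: "neutral", 1: "cation", -1: "anion"}[self.net_charge]

    @property
    def formula_string(self) -> str:
        return formula_to_string(self.formula)


@dataclass
class RejectionRecord:
    source_id: str
    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class IonSpecies:
    """An adduct the compound will be (or was) ionized as."""

    adduct_label: str
    polarity: str
    mz: float


# ---------------------------------------------------------------------------
# structure normalization

_UNCHARGER = rdMolStandardize.Uncharger()


def _distinct_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    seen: dict[str, Chem.Mol] = {}
    for frag in frags:
        seen.setdefault(Chem.MolToSmiles(frag), frag)
    return list(seen.values())


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def normalize_structure(
    smiles_raw: str, source_id: str = "", name: str = ""
) -> MsReadyCompound | RejectionRecord:
    """Desalt, neutralize and canonicalize one raw SMILES.

    Desalting strips recognized counter-ion / solvent fragments: every
    carbon-free fragment is treated as a counter-ion when at least one
    carbon-bearing fragment is present.  A record whose structure is
    still multi-component afterwards — two or more distinct organic
    fragments, i.e. a "." survives in the canonical string — is rejected
    as ``residual_salt``, as is one left empty.  Neutralization is
    rule-based (de)protonation; permanent charges such as quaternary
    ammonium survive it.
    """
    if not smiles_raw or not smiles_raw.strip():
        return RejectionRecord(source_id, "no_structure", "empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return RejectionRecord(source_id, "unparsable", f"RDKit failed on {smiles_raw!r}")

    fragments = _distinct_fragments(mol)
    organic = [f for f in fragments if _has_carbon(f)]
    if len(organic) >= 2:
        return RejectionRecord(
            source_id, "residual_salt",
            f"{len(organic)} organic components after desalting",
        )
    if organic:
        parent = organic[0]
    elif len(fragments) == 1:
        parent = fragments[0]  # single inorganic species, e.g. water
    elif fragments:
        return RejectionRecord(
            source_id, "residual_salt", "multi-component inorganic salt"
        )
    else:
        return RejectionRecord(source_id, "residual_salt", "empty after desalting")

    try:
        Chem.SanitizeMol(parent)
        parent = _UNCHARGER.uncharge(parent)
    except Exception as exc:  # valence errors surfaced by sanitization
        return RejectionRecord(source_id, "unparsable", str(exc))

    smiles = Chem.MolToSmiles(parent)
    if "." in smiles:
        return RejectionRecord(source_id, "residual_salt", "canonical form multi-component")

    formula: Counter[str] = Counter()
    atom_count = 0
    for atom in parent.GetAtoms():
        formula[atom.GetSymbol()] += 1
        atom_count += 1
        h = atom.GetTotalNumHs()
        if h:
            formula["H"] += h
            atom_count += h
    try:
        mass = monoisotopic_mass(dict(formula))
    except ValueError as exc:
        return RejectionRecord(source_id, "unparsable", str(exc))

    return MsReadyCompound(
        source_id=source_id,
        smiles_canonical=smiles,
        formula=dict(formula),
        monoisotopic_mass=mass,
        net_charge=Chem.GetFormalCharge(parent),
        atom_count=atom_count,
        name=name,
    )


def apply_filters(compound: MsReadyCompound) -> MsReadyCompound | RejectionRecord:
    """Reject, in fixed order: mass < 40 Da, mass > 1000 Da, more than
    200 atoms, net charge of magnitude >= 2.  Order is fixed so that
    per-reason counts are reproducible run to run."""
    m = compound.monoisotopic_mass
    if m < MASS_MIN_DA:
        return RejectionRecord(compound.source_id, "mass_below_min", f"{m:.4f} Da")
    if m > MASS_MAX_DA:
        return RejectionRecord(compound.source_id, "mass_above_max", f"{m:.4f} Da")
    if compound.atom_count > ATOM_MAX:
        return RejectionRecord(
            compound.source_id, "too_many_atoms", f"{compound.atom_count} atoms"
        )
    if abs(compound.net_charge) >= 2:
        return RejectionRecord(
            compound.source_id, "multiply_charged", f"charge {compound.net_charge:+d}"
        )
    return compound


def deduplicate(
    compounds: Sequence[MsReadyCompound],
) -> tuple[list[MsReadyCompound], list[RejectionRecord]]:
    """Merge records with identical canonical SMILES by exact string
    comparison.  First occurrence wins; later occurrences become
    ``duplicate`` rejections and their source_ids are kept as
    cross-references on the survivor.  Stereoisomers with distinct
    canonical strings are all kept."""
    kept: dict[str, MsReadyCompound] = {}
    order: list[str] = []
    rejected: list[RejectionRecord] = []
    for c in compounds:
        survivor = kept.get(c.smiles_canonical)
        if survivor is None:
            kept[c.smiles_canonical] = replace(c, cross_refs=list(c.cross_refs))
            order.append(c.smiles_canonical)
        else:
            survivor.cross_refs.append(c.source_id)
            rejected.append(
                RejectionRecord(c.source_id, "duplicate", f"of {survivor.source_id}")
            )
    return [kept[s] for s in order], rejected


def classify_ion_species(compound: MsReadyCompound) -> list[IonSpecies]:
    """Ion species a single-charge predictor will compute for this
    compound: neutrals get protonated/deprotonated species in both
    polarities, native ions get only their own [M]+/[M]- species."""
    m = compound.monoisotopic_mass
    if compound.net_charge == 0:
        return [
            IonSpecies("[M+H]+", "positive", precursor_mz(m, "[M+H]+")),
            IonSpecies("[M-H]-", "negative", precursor_mz(m, "[M-H]-")),
        ]
    if compound.net_charge == 1:
        return [IonSpecies("[M]+", "positive", precursor_mz(m, "[M]+"))]
    if compound.net_charge == -1:
        return [IonSpecies("[M]-", "negative", precursor_mz(m, "[M]-"))]
    raise ValueError(
        f"{compound.source_id}: |charge| >= 2 must be filtered before ion classification"
    )


# ---------------------------------------------------------------------------
# structure resolution for records without SMILES

ResolverFn = Callable[[str, str], "str | None"]


class MappingResolver:
    """Offline resolver backed by an identifier -> SMILES mapping.
    Stands in for a remote PubChem lookup in tests and air-gapped runs."""

    def __init__(self, mapping: Mapping[str, str]):
        self._mapping = dict(mapping)

    def __call__(self, kind: str, value: str) -> str | None:
        return self._mapping.get(value)


class PubChemResolver:
    """Live PubChem PUG REST lookup (name / CAS / InChI / InChIKey ->
    canonical SMILES).  Network failures degrade to a miss so the
    pipeline continues."""

    _URL = "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/{ns}/{value}/property/CanonicalSMILES/TXT"
    _NAMESPACE = {"name": "name", "cas": "name", "inchikey": "inchikey", "inchi": "inchi"}

    def __init__(self, timeout: float = 10.0):
        self.timeout = timeout

    def __call__(self, kind: str, value: str) -> str | None:
        import urllib.parse
        import urllib.request

        ns = self._NAMESPACE.get(kind)
        if ns is None:
            return None
        url = self._URL.format(ns=ns, value=urllib.parse.quote(value, safe=""))
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                text = resp.read().decode().strip().splitlines()
                return text[0] if text else None
        except Exception:
            return None


def resolve_missing_structures(
    records: Iterable[CompoundRecord], resolver: ResolverFn
) -> list[CompoundRecord]:
    """Fill in missing SMILES by querying name, CAS, InChI and InChIKey
    in that order.  Existing SMILES are never overwritten; unresolved
    records pass through unchanged (they are rejected as
    ``no_structure`` downstream)."""
    out: list[CompoundRecord] = []
    for rec in records:
        if rec.smiles_raw:
            out.append(rec)
            continue
        smiles = None
        for kind in ("name", "cas", "inchi", "inchikey"):
            value = getattr(rec, "inchikey" if kind == "inchikey" else kind)
            if value:
                smiles = resolver(kind, value)
                if smiles:
                    break
        out.append(replace(rec, smiles_raw=smiles) if smiles else rec)
    return out


# ---------------------------------------------------------------------------
# full cascade

@dataclass
class CleanupResult:
    compounds: list[MsReadyCompound]
    rejections: list[RejectionRecord]
    n_input: int

    @property
    def summary(self) -> dict[str, int]:
        counts = Counter(r.reason for r in self.rejections)
        out = {reason: counts.get(reason, 0) for reason in REJECTION_REASONS}
        out["kept"] = len(self.compounds)
        out["input"] = self.n_input
        return out

    def ion_groups(self) -> dict[str, int]:
        groups = Counter(c.ion_class for c in self.compounds)
        return {k: groups.get(k, 0) for k in ("neutral", "cation", "anion")}


def clean_table(
    records: Sequence[CompoundRecord], resolver: ResolverFn | None = None
) -> CleanupResult:
    """Run the full cascade: optional structure resolution, then
    normalize -> filter -> deduplicate.  Conservation holds:
    ``len(records) == len(compounds) + len(rejections)``."""
    if resolver is not None:
        records = resolve_missing_structures(records, resolver)
    normalized: list[MsReadyCompound] = []
    rejections: list[RejectionRecord] = []
    for rec in records:
        result = normalize_structure(rec.smiles_raw, rec.source_id, rec.name)
        if isinstance(result, RejectionRecord):
            rejections.append(result)
            continue
        result = apply_filters(result)
        (normalized if isinstance(result, MsReadyCompound) else rejections).append(result)
    unique, dup_rejections = deduplicate(normalized)
    rejections.extend(dup_rejections)
    return CleanupResult(unique, rejections, len(records))


# ---------------------------------------------------------------------------
# tabular I/O

DEFAULT_COLUMNS = {
    "source_id": ("source_id", "id", "norman_susdat_id", "susdat_id"),
    "name": ("name", "compound_name"),
    "smiles_raw": ("smiles_raw", "smiles"),
    "inchi": ("inchi", "std_inchi"),
    "inchikey": ("inchikey", "std_inchikey"),
    "cas": ("cas", "cas_rn", "cas_no"),
}


def read_compound_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a delimited compound table (CSV or TSV, sniffed).  ``columns``
    maps CompoundRecord field -> column name; unmapped fields fall back
    to case-insensitive matching against common header spellings."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for fld, synonyms in DEFAULT_COLUMNS.items():
        if columns and fld in columns:
            resolved[fld] = columns[fld]
        else:
            for syn in synonyms:
                if syn in lower:
                    resolved[fld] = lower[syn]
                    break
    if "source_id" not in resolved:
        raise ValueError(f"no ID column found in {path} (headers: {list(df.columns)})")
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                **{fld: str(row[col]).strip() for fld, col in resolved.items()}
            )
        )
    return records


def read_msready_table(path: str | Path) -> list[MsReadyCompound]:
    """Read back an MS-ready compound table written by
    :func:`write_cleanup_outputs`."""
    from .masses import parse_formula

    compounds: list[MsReadyCompound] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            compounds.append(
                MsReadyCompound(
                    source_id=row["source_id"],
                    name=row.get("name", ""),
                    smiles_canonical=row["smiles_canonical"],
                    formula=parse_formula(row["formula"]),
                    monoisotopic_mass=float(row["monoisotopic_mass"]),
                    net_charge=int(row["net_charge"]),
                    atom_count=int(row["atom_count"]),
                    cross_refs=[x for x in row.get("cross_refs", "").split(";") if x],
                )
            )
    return compounds


def write_cleanup_outputs(result: CleanupResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the MS-ready table, rejection report and JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    compounds_path = out_dir / "msready_compounds.csv"
    with compounds_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["source_id", "name", "smiles_canonical", "formula",
             "monoisotopic_mass", "net_charge", "atom_count", "ion_class", "cross_refs"]
        )
        for c in result.compounds:
            w.writerow(
                [c.source_id, c.name, c.smiles_canonical, c.formula_string,
                 repr(c.monoisotopic_mass), c.net_charge, c.atom_count,
                 c.ion_class, ";".join(c.cross_refs)]
            )
    rejections_path = out_dir / "rejections.csv"
    with rejections_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "reason", "detail"])
        for r in result.rejections:
            w.writerow([r.source_id, r.reason, r.detail])
    summary_path = out_dir / "cleanup_summary.json"
    summary = dict(result.summary)
    summary["ion_groups"] = result.ion_groups()
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "compounds": compounds_path,
        "rejections": rejections_path,
        "summary": summary_path,
    }
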