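"""Monoisotopic masses and adduct m/z arithmetic.

All precursor and fragment m/z values in the package derive from the
isotope table below (most-abundant-isotope masses, CODATA/NIST 2021
atomic mass evaluation, truncated at 1e-7 Da) together with the proton
and electron masses.  High-resolution suspect screening works at ppm
accuracy, so six decimal places are required and carried throughout.
"""

from __future__ import annotations

import re

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MONOISOTOPIC",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "precursor_mz",
    "SUPPORTED_ADDUCTS",
    "ppm_difference",
]

#: Mass of a proton in Da (H atom minus one electron).
PROTON_MASS = 1.00727646

#: Electron rest mass in Da; applied when forming native [M]+/[M]- ions.
ELECTRON_MASS = 0.00054858

#: Most-abundant-isotope atomic masses (Da).  AME2020 values.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "Si": 27.9769265,
    "P": 30.9737615,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625909,
    "Fe": 55.9349363,
    "Cu": 62.9295977,
    "Zn": 63.9291420,
    "Br": 78.9183376,
    "I": 126.9044719,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula (e.g. ``"C12H20N4O2"``)
    into an element -> count map.

    Raises :class:`ValueError` on symbols absent from the isotope table
    or on text that is not a plain element/count sequence.
    """
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element = m.group(1)
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element symbol {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def formula_to_string(counts: dict[str, int]) -> str:
    """Hill order: C, H, then alphabetical."""
    parts = []
    for el in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
        n = counts.get(el, 0)
        if n > 0:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic (exact) mass in Da of an elemental composition.

    Accepts either an element->count map or a formula string.  An empty
    composition has mass 0.0.  Unknown element symbols raise
    :class:`ValueError` naming the symbol.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = 0.0
    for element, count in formula.items():
        try:
            mass += MONOISOTOPIC[element] * count
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return mass


# neutral-mass offset applied per adduct label
_FORMIC_ACID = 12.0 + 2 * MONOISOTOPIC["H"] + 2 * MONOISOTOPIC["O"]  # CH2O2

_ADDUCT_OFFSETS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M]+": -ELECTRON_MASS,
    "[M]-": ELECTRON_MASS,
    # formate adduct seen for per-/polyfluorinated diols in negative mode
    "[M+CH2O2-H]-": _FORMIC_ACID - PROTON_MASS,
    "[M+HCOO]-": _FORMIC_ACID - PROTON_MASS,
}

SUPPORTED_ADDUCTS = tuple(_ADDUCT_OFFSETS)


def precursor_mz(mass: float, adduct_label: str) -> float:
    """m/z of an ion species formed from a neutral (or native ion) of
    monoisotopic mass ``mass``.

    ``[M+H]+``/``[M-H]-`` add/remove a proton; native ``[M]+``/``[M]-``
    only correct for the electron mass.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    try:
        return mass + _ADDUCT_OFFSETS[adduct_label]
    except KeyError:
        raise ValueError(
            f"unknown adduct label {adduct_label!r}; supported: {', '.join(_ADDUCT_OFFSETS)}"
        ) from None


def ppm_difference(observed: float, reference: float) -> float:
    """Signed relative deviation of ``observed`` from ``reference`` in ppm."""
    return (observed - reference) / reference * 1e6
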