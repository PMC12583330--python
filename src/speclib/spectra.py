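"""Spectrum and spectral-library containers.

A :class:`Spectrum` is an ascending-m/z peak list with precursor,
adduct, polarity, collision energy and compound metadata.  A
:class:`SpectralLibrary` is an ordered collection with a precursor-m/z
sorted index so candidate retrieval within a ppm window is a binary
search, not a scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Peak", "Spectrum", "SpectralLibrary"]

PREDICTED_ENERGIES = (10.0, 20.0, 40.0)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be nonnegative, got {self.intensity}")


@dataclass
class Spectrum:
    compound_id: str
    peaks: list[Peak]
    precursor_mz: float
    adduct_label: str = ""
    polarity: str = ""
    collision_energy: float = 0.0
    provenance: str = "experimental"
    formula: str = ""
    smiles: str = ""
    inchi: str = ""
    inchikey: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)

    def copy(self, **changes) -> "Spectrum":
        changes.setdefault("peaks", list(self.peaks))
        return replace(self, **changes)


class SpectralLibrary:
    """Ordered spectrum collection with ppm-window precursor retrieval.

    Iteration order is insertion order; the precursor index is rebuilt
    lazily after appends.
    """

    def __init__(self, entries: Iterable[Spectrum] = ()):  # noqa: D107
        self.entries: list[Spectrum] = list(entries)
        self._index_dirty = True
        self._sorted_mz: np.ndarray | None = None
        self._sorted_pos: np.ndarray | None = None

    def append(self, spectrum: Spectrum) -> None:
        self.entries.append(spectrum)
        self._index_dirty = True

    def extend(self, spectra: Iterable[Spectrum]) -> None:
        self.entries.extend(spectra)
        self._index_dirty = True

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> Spectrum:
        return self.entries[i]

    def _rebuild_index(self) -> None:
        mz = np.array([s.precursor_mz for s in self.entries])
        order = np.argsort(mz, kind="stable")
        self._sorted_mz = mz[order]
        self._sorted_pos = order
        self._index_dirty = False

    def query_precursor(
        self, mz: float, tol_ppm: float, polarity: str | None = None
    ) -> list[Spectrum]:
        """All spectra whose precursor lies within ``tol_ppm`` of ``mz``
        (window relative to the query m/z), optionally restricted by
        polarity.  Returned in library insertion order."""
        if not self.entries:
            return []
        if self._index_dirty:
            self._rebuild_index()
        delta = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self._sorted_mz, mz - delta, side="left")
        hi = np.searchsorted(self._sorted_mz, mz + delta, side="right")
        positions = sorted(self._sorted_pos[lo:hi])
        hits = [self.entries[p] for p in positions]
        if polarity:
            hits = [s for s in hits if s.polarity == polarity]
        return hits

    def by_compound(self) -> dict[str, list[Spectrum]]:
        groups: dict[str, list[Spectrum]] = {}
        for s in self.entries:
            groups.setdefault(s.compound_id, []).append(s)
        return groups
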