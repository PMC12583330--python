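"""MS2 spectral matching: peak alignment, cosine similarity, explained
intensity, matched-fragment counting, and dual-threshold decisions.

The similarity statistic is the unweighted cosine

    cos(theta) = v . u / (|v| |u|)

where ``v`` and ``u`` are the query (experimental) and reference
intensity vectors after ppm-tolerance alignment.  Unmatched peaks on
either side are kept and matched to zero, so a contaminated query is
penalized in cosine but — by construction — leaves the reference-side
explained intensity untouched.  That asymmetry is the reason the
accept/reject decision uses both statistics: a low cosine with high
explained intensity signals interference rather than non-similarity,
which is exactly the regime where predicted (in-silico) libraries still
produce true positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, SpectralLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPair",
    "PeakAlignment",
    "MatchScores",
    "ThresholdProfile",
    "PROFILES",
    "AnnotationDecision",
    "align_peaks",
    "cosine_score",
    "explained_intensity",
    "count_matched_fragments",
    "score_alignment",
    "match_feature",
    "decide",
    "annotate",
]


@dataclass(frozen=True)
class AlignedPair:
    query_index: int | None
    reference_index: int | None
    mz_query: float | None
    mz_reference: float | None
    i_query: float
    i_reference: float


@dataclass
class PeakAlignment:
    """One-to-one pairing of query and reference peaks.  Every peak of
    both spectra appears in exactly one pair; unmatched peaks carry a
    zero partner intensity."""

    pairs: list[AlignedPair]
    n_matched: int
    precursor_matched: bool
    query_precursor_mz: float
    fragment_tol_ppm: float

    @property
    def v(self) -> np.ndarray:
        """Query intensity vector."""
        return np.array([p.i_query for p in self.pairs])

    @property
    def u(self) -> np.ndarray:
        """Reference intensity vector."""
        return np.array([p.i_reference for p in self.pairs])


def align_peaks(
    query: Spectrum,
    reference: Spectrum,
    fragment_tol_ppm: float = 5.0,
    precursor_tol_ppm: float = 3.0,
) -> PeakAlignment:
    """Greedy one-to-one peak pairing by smallest ppm deviation.

    All (query, reference) peak pairs within ``fragment_tol_ppm`` of
    each other (deviation relative to the reference m/z) are candidate
    matches; they are consumed best-first, ties broken by larger
    reference intensity, then lower indices.  Residual peaks from both
    sides are appended as zero-partnered pairs.
    """
    q_mz, q_int = query.mz, query.intensity
    r_mz, r_int = reference.mz, reference.intensity
    candidates: list[tuple[float, float, int, int]] = []
    for qi in range(len(q_mz)):
        # reference peaks within absolute window of this query peak
        delta = r_mz * fragment_tol_ppm * 1e-6
        close = np.nonzero(np.abs(q_mz[qi] - r_mz) <= delta)[0]
        for ri in close:
            dev = abs(q_mz[qi] - r_mz[ri]) / r_mz[ri] * 1e6
            candidates.append((dev, -r_int[ri], qi, int(ri)))
    candidates.sort()

    q_used = [False] * len(q_mz)
    r_used = [False] * len(r_mz)
    matched: list[tuple[int, int]] = []
    for _, _, qi, ri in candidates:
        if not q_used[qi] and not r_used[ri]:
            q_used[qi] = r_used[ri] = True
            matched.append((qi, ri))
    matched.sort()

    pairs = [
        AlignedPair(qi, ri, q_mz[qi], r_mz[ri], q_int[qi], r_int[ri])
        for qi, ri in matched
    ]
    for qi in range(len(q_mz)):
        if not q_used[qi]:
            pairs.append(AlignedPair(qi, None, q_mz[qi], None, q_int[qi], 0.0))
    for ri in range(len(r_mz)):
        if not r_used[ri]:
            pairs.append(AlignedPair(None, ri, None, r_mz[ri], 0.0, r_int[ri]))

    precursor_matched = bool(
        query.precursor_mz > 0
        and reference.precursor_mz > 0
        and abs(query.precursor_mz - reference.precursor_mz)
        <= reference.precursor_mz * precursor_tol_ppm * 1e-6
    )
    return PeakAlignment(
        pairs=pairs,
        n_matched=len(matched),
        precursor_matched=precursor_matched,
        query_precursor_mz=query.precursor_mz,
        fragment_tol_ppm=fragment_tol_ppm,
    )


def cosine_score(alignment: PeakAlignment) -> float:
    """Unweighted cosine of the aligned intensity vectors.  A zero-norm
    vector on either side yields 0 with a warning."""
    v, u = alignment.v, alignment.u
    norm = math.sqrt(float(v @ v)) * math.sqrt(float(u @ u))
    if norm == 0.0:
        logger.warning("cosine on zero-norm intensity vector; returning 0")
        return 0.0
    return float(v @ u) / norm


def explained_intensity(alignment: PeakAlignment, side: str = "reference") -> float:
    """Fraction of one spectrum's total intensity carried by peaks that
    found a (nonzero) partner on the other side.

    The default side is the reference: contaminant peaks present only
    in the query then cannot depress the value, so it separates
    interference-induced low cosines from genuine dissimilarity.
    """
    if side not in ("reference", "query"):
        raise ValueError(f"side must be 'reference' or 'query', got {side!r}")
    own = alignment.u if side == "reference" else alignment.v
    other = alignment.v if side == "reference" else alignment.u
    total = float(own.sum())
    if total <= 0:
        raise ValueError(f"{side} spectrum has zero total intensity")
    explained = float(own[other > 0].sum())
    return explained / total


def count_matched_fragments(alignment: PeakAlignment) -> int:
    """Matched fragment pairs, plus one for a matched precursor unless
    the precursor is already present among the matched peaks (no double
    counting)."""
    n = alignment.n_matched
    if alignment.precursor_matched:
        tol = alignment.query_precursor_mz * alignment.fragment_tol_ppm * 1e-6
        precursor_as_peak = any(
            p.query_index is not None
            and p.reference_index is not None
            and abs(p.mz_query - alignment.query_precursor_mz) <= tol
            for p in alignment.pairs
        )
        if not precursor_as_peak:
            n += 1
    return n


@dataclass(frozen=True)
class ThresholdProfile:
    """Decision thresholds and tolerances for one annotation run."""

    min_cosine: float
    min_explained_intensity: float
    min_matched_fragments: int = 2
    precursor_tol_ppm: float = 3.0
    fragment_tol_ppm: float = 5.0
    min_report_score: float = 0.1
    explained_intensity_side: str = "reference"


#: Named presets: "experimental" reflects the community-consensus 0.7
#: cosine floor (with a strict explained-intensity companion) for
#: measured reference libraries; "in_silico" lowers the cosine floor to
#: 0.2 and leans on explained intensity >= 0.7 instead, the operating
#: point appropriate for predicted spectra.
PROFILES: dict[str, ThresholdProfile] = {
    "experimental": ThresholdProfile(min_cosine=0.7, min_explained_intensity=0.9),
    "in_silico": ThresholdProfile(min_cosine=0.2, min_explained_intensity=0.7),
}


@dataclass
class MatchScores:
    reference_id: str
    cosine: float
    explained_intensity: float
    n_matched_fragments: int
    collision_energy_used: float = 0.0
    adduct_label: str = ""
    query_id: str = ""


@dataclass
class AnnotationDecision:
    query_id: str
    candidate: str
    scores: MatchScores
    verdict: str
    reasons: list[str] = field(default_factory=list)


def score_alignment(
    query: Spectrum, reference: Spectrum, profile: ThresholdProfile
) -> MatchScores:
    alignment = align_peaks(
        query, reference, profile.fragment_tol_ppm, profile.precursor_tol_ppm
    )
    try:
        ei = explained_intensity(alignment, profile.explained_intensity_side)
    except ValueError:
        ei = 0.0
    return MatchScores(
        reference_id=reference.compound_id,
        cosine=cosine_score(alignment),
        explained_intensity=ei,
        n_matched_fragments=count_matched_fragments(alignment),
        collision_energy_used=reference.collision_energy,
        adduct_label=reference.adduct_label,
        query_id=query.compound_id,
    )


def match_feature(
    query: Spectrum, library: SpectralLibrary, profile: ThresholdProfile
) -> list[MatchScores]:
    """Score one query feature against all library candidates.

    Candidates are spectra with matching polarity and a precursor
    within tolerance.  Each candidate compound is scored at every
    available collision energy and the best-cosine energy is retained
    (ties: higher explained intensity, then lower energy).  Results
    below the reporting floor or the fragment minimum are dropped; the
    rest are ranked by descending cosine, ties by explained intensity
    then reference_id.
    """
    if query.precursor_mz <= 0:
        raise ValueError(f"query {query.compound_id!r} has no precursor m/z")
    candidates = library.query_precursor(
        query.precursor_mz, profile.precursor_tol_ppm, query.polarity or None
    )
    best: dict[str, MatchScores] = {}
    for reference in candidates:
        scores = score_alignment(query, reference, profile)
        prev = best.get(reference.compound_id)
        if prev is None or (
            scores.cosine,
            scores.explained_intensity,
            -scores.collision_energy_used,
        ) > (prev.cosine, prev.explained_intensity, -prev.collision_energy_used):
            best[reference.compound_id] = scores
    results = [
        s
        for s in best.values()
        if s.cosine >= profile.min_report_score
        and s.n_matched_fragments >= profile.min_matched_fragments
    ]
    results.sort(key=lambda s: (-s.cosine, -s.explained_intensity, s.reference_id))
    return results


def decide(scores: MatchScores, profile: ThresholdProfile) -> AnnotationDecision:
    """Dual-threshold verdict: accepted iff cosine, explained intensity
    and fragment count all meet the profile; a match failing only the
    cosine floor while explained intensity holds becomes a candidate
    for manual curation; anything else is rejected."""
    reasons = []
    if scores.cosine < profile.min_cosine:
        reasons.append("min_cosine")
    if scores.explained_intensity < profile.min_explained_intensity:
        reasons.append("min_explained_intensity")
    if scores.n_matched_fragments < profile.min_matched_fragments:
        reasons.append("min_matched_fragments")
    if not reasons:
        verdict = "accepted"
    elif reasons == ["min_cosine"]:
        verdict = "candidate_for_curation"
    else:
        verdict = "rejected"
    return AnnotationDecision(
        query_id=scores.query_id,
        candidate=scores.reference_id,
        scores=scores,
        verdict=verdict,
        reasons=reasons,
    )


def annotate(
    queries: SpectralLibrary | list[Spectrum],
    library: SpectralLibrary,
    profile: ThresholdProfile,
):
    """Annotate a batch of query features; returns a pandas DataFrame
    with one row per reported (query, candidate) pair."""
    import pandas as pd

    rows = []
    for query in queries:
        for rank, scores in enumerate(match_feature(query, library, profile), start=1):
            decision = decide(scores, profile)
            rows.append(
                {
                    "query_id": query.compound_id,
                    "reference_id": scores.reference_id,
                    "adduct": scores.adduct_label,
                    "rank": rank,
                    "cosine": scores.cosine,
                    "explained_intensity": scores.explained_intensity,
                    "n_fragments": scores.n_matched_fragments,
                    "energy": scores.collision_energy_used,
                    "verdict": decision.verdict,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "reference_id", "adduct", "rank", "cosine",
            "explained_intensity", "n_fragments", "energy", "verdict",
        ],
    )
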