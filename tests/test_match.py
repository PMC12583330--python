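"""Peak alignment, cosine scoring, explained intensity, fragment
counting, candidate ranking and dual-threshold decisions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speclib import (
    CorruptionConfig,
    Peak,
    PROFILES,
    Spectrum,
    SpectralLibrary,
    align_peaks,
    corrupt_spectrum,
    cosine_score,
    count_matched_fragments,
    decide,
    explained_intensity,
    generate_reference_spectrum,
    match_feature,
)
from speclib.match import MatchScores, ThresholdProfile, score_alignment


def _spectrum(cid, mzs, intensities, precursor, polarity="positive", energy=0.0):
    return Spectrum(cid, [Peak(m, i) for m, i in zip(mzs, intensities)],
                    precursor, polarity=polarity, collision_energy=energy)


class TestAlignment:
    def test_within_tolerance_matches(self):
        q = _spectrum("q", [100.0000], [1.0], 200.0)
        r = _spectrum("r", [100.0004], [1.0], 200.0)
        a = align_peaks(q, r, fragment_tol_ppm=5.0)  # deviation 4 ppm
        assert a.n_matched == 1

    def test_outside_tolerance_kept_matched_to_zero(self):
        q = _spectrum("q", [100.0000], [1.0], 200.0)
        r = _spectrum("r", [100.0010], [1.0], 200.0)  # 10 ppm
        a = align_peaks(q, r, fragment_tol_ppm=5.0)
        assert a.n_matched == 0
        assert len(a.pairs) == 2
        assert {(p.i_query, p.i_reference) for p in a.pairs} == {(1.0, 0.0), (0.0, 1.0)}

    def test_empty_reference_all_unmatched(self):
        q = _spectrum("q", [100.0, 200.0], [1.0, 2.0], 300.0)
        r = Spectrum("r", [], 300.0)
        a = align_peaks(q, r)
        assert a.n_matched == 0
        assert len(a.pairs) == 2

    def test_one_to_one_tie_prefers_intense_reference(self):
        # one query peak equidistant from two reference peaks
        q = _spectrum("q", [100.0000], [1.0], 200.0)
        r = _spectrum("r", [99.99980, 100.00020], [5.0, 50.0], 200.0)
        a = align_peaks(q, r, fragment_tol_ppm=5.0)
        matched = [p for p in a.pairs if p.query_index is not None and p.reference_index is not None]
        assert len(matched) == 1
        assert matched[0].i_reference == 50.0

    def test_every_peak_in_exactly_one_pair(self):
        ref = generate_reference_spectrum(400.0, 10, seed=3)
        query = corrupt_spectrum(ref, CorruptionConfig(seed=4))
        a = align_peaks(query, ref)
        q_idx = [p.query_index for p in a.pairs if p.query_index is not None]
        r_idx = [p.reference_index for p in a.pairs if p.reference_index is not None]
        assert sorted(q_idx) == list(range(len(query.peaks)))
        assert sorted(r_idx) == list(range(len(ref.peaks)))


class TestCosine:
    def test_identity_and_orthogonality(self, toy_pair):
        ref = generate_reference_spectrum(300.0, 8, seed=1)
        assert cosine_score(align_peaks(ref, ref)) == pytest.approx(1.0)
        q = _spectrum("q", [101.0, 102.0], [1.0, 1.0], 300.0)
        r = _spectrum("r", [201.0, 202.0], [1.0, 1.0], 300.0)
        assert cosine_score(align_peaks(q, r)) == 0.0

    def test_hand_computed_value(self, toy_pair):
        # v=(100,50,0), u=(100,100,50): 15000 / (sqrt(12500) sqrt(22500))
        query, reference = toy_pair
        a = align_peaks(query, reference)
        assert cosine_score(a) == pytest.approx(0.894427, abs=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=1e-3, max_value=1e3), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, alpha, seed):
        ref = generate_reference_spectrum(350.0, 6, seed=seed % 1000)
        query = corrupt_spectrum(ref, CorruptionConfig(seed=seed % 997))
        scaled = query.copy(peaks=[Peak(p.mz, p.intensity * alpha) for p in query.peaks])
        c1 = cosine_score(align_peaks(query, ref))
        c2 = cosine_score(align_peaks(scaled, ref))
        assert c2 == pytest.approx(c1, abs=1e-9)
        assert 0.0 <= c1 <= 1.0 + 1e-12

    def test_symmetry(self):
        for seed in range(5):
            ref = generate_reference_spectrum(350.0, 7, seed=seed)
            query = corrupt_spectrum(ref, CorruptionConfig(seed=seed + 50))
            assert cosine_score(align_peaks(query, ref)) == pytest.approx(
                cosine_score(align_peaks(ref, query)), abs=1e-9
            )


class TestExplainedIntensity:
    def test_all_reference_matched_is_one(self):
        ref = generate_reference_spectrum(300.0, 6, seed=2)
        assert explained_intensity(align_peaks(ref, ref)) == pytest.approx(1.0)

    def test_partial_fraction(self, toy_pair):
        # matched reference intensity 200 of total 250
        query, reference = toy_pair
        a = align_peaks(query, reference)
        assert explained_intensity(a, "reference") == pytest.approx(200 / 250)
        assert explained_intensity(a, "query") == pytest.approx(1.0)

    def test_contaminants_leave_reference_side_unchanged(self):
        ref = generate_reference_spectrum(400.0, 8, seed=6)
        chimeric_only = CorruptionConfig(
            ppm_jitter_sd=0.0, intensity_noise_cv=0.0, dropout_p=0.0,
            n_chimeric=5, seed=8,
        )
        query = corrupt_spectrum(ref, chimeric_only)
        a = align_peaks(query, ref)
        assert explained_intensity(a, "reference") == pytest.approx(1.0)
        assert cosine_score(a) < 1.0

    def test_zero_total_intensity_errors(self):
        q = _spectrum("q", [100.0], [1.0], 200.0)
        r = _spectrum("r", [100.0], [0.0], 200.0)
        with pytest.raises(ValueError):
            explained_intensity(align_peaks(q, r), "reference")


class TestMatchedFragments:
    def test_precursor_counts_once(self):
        # one matched fragment + matched precursor (not among peaks) -> 2
        q = _spectrum("q", [100.0], [1.0], 250.0)
        r = _spectrum("r", [100.0], [1.0], 250.0)
        assert count_matched_fragments(align_peaks(q, r)) == 2

    def test_no_double_count_when_precursor_is_a_peak(self):
        q = _spectrum("q", [100.0, 250.0], [1.0, 5.0], 250.0)
        r = _spectrum("r", [100.0, 250.0], [1.0, 5.0], 250.0)
        assert count_matched_fragments(align_peaks(q, r)) == 2

    def test_single_fragment_unmatched_precursor_fails_minimum(self):
        # the sparse negative-mode regime: 1 matching fragment only
        q = _spectrum("q", [100.0], [1.0], 250.0)
        r = _spectrum("r", [100.0], [1.0], 251.0)  # precursor off by ~4000 ppm
        a = align_peaks(q, r)
        assert count_matched_fragments(a) == 1
        assert count_matched_fragments(a) < PROFILES["in_silico"].min_matched_fragments

    def test_nothing_matched_is_zero(self):
        q = _spectrum("q", [100.0], [1.0], 250.0)
        r = _spectrum("r", [120.0], [1.0], 260.0)
        assert count_matched_fragments(align_peaks(q, r)) == 0


class TestChimericMonotonicity:
    def test_cosine_never_increases_with_contamination(self):
        ref = generate_reference_spectrum(450.0, 10, seed=12)
        previous = 1.0
        for n_chim in (0, 2, 4, 8, 16):
            config = CorruptionConfig(
                ppm_jitter_sd=0.0, intensity_noise_cv=0.0, dropout_p=0.0,
                n_chimeric=n_chim, seed=13,
            )
            query = corrupt_spectrum(ref, config)
            a = align_peaks(query, ref)
            c = cosine_score(a)
            assert c <= previous + 1e-12
            assert explained_intensity(a, "reference") == pytest.approx(1.0)
            previous = c


def _oracle_cosine(query, reference, tol_ppm=5.0):
    """Exhaustive optimal one-to-one assignment: maximize matches, then
    minimize total ppm deviation, over all injective pairings."""
    q_mz, q_int = query.mz, query.intensity
    r_mz, r_int = reference.mz, reference.intensity
    valid = {}
    for qi, ri in itertools.product(range(len(q_mz)), range(len(r_mz))):
        dev = abs(q_mz[qi] - r_mz[ri]) / r_mz[ri] * 1e6
        if dev <= tol_ppm:
            valid[(qi, ri)] = dev

    best = (-1, math.inf, [])
    q_indices = list(range(len(q_mz)))

    def search(qi, used_r, n, total, pairs):
        nonlocal best
        if qi == len(q_indices):
            if n > best[0] or (n == best[0] and total < best[1]):
                best = (n, total, list(pairs))
            return
        search(qi + 1, used_r, n, total, pairs)  # leave qi unmatched
        for ri in range(len(r_mz)):
            if (qi, ri) in valid and ri not in used_r:
                pairs.append((qi, ri))
                search(qi + 1, used_r | {ri}, n + 1, total + valid[(qi, ri)], pairs)
                pairs.pop()

    search(0, frozenset(), 0, 0.0, [])
    _, _, pairs = best
    matched_q = {qi for qi, _ in pairs}
    matched_r = {ri for _, ri in pairs}
    v = [q_int[qi] for qi, _ in pairs] + [q_int[qi] for qi in range(len(q_mz)) if qi not in matched_q]
    u = [r_int[ri] for _, ri in pairs] + [0.0] * (len(q_mz) - len(matched_q))
    v += [0.0] * (len(r_mz) - len(matched_r))
    u += [r_int[ri] for ri in range(len(r_mz)) if ri not in matched_r]
    v, u = np.array(v), np.array(u)
    norm = np.linalg.norm(v) * np.linalg.norm(u)
    return float(v @ u) / norm if norm else 0.0, len(pairs)


class TestGreedyVsOptimalOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_equals_exhaustive_on_small_spectra(self, seed):
        rng = np.random.default_rng(seed)
        n_ref = int(rng.integers(2, 9))
        ref = generate_reference_spectrum(300.0 + seed, n_ref, seed=seed)
        query = corrupt_spectrum(
            ref,
            CorruptionConfig(ppm_jitter_sd=1.5, intensity_noise_cv=0.3,
                             dropout_p=0.2, n_chimeric=2, seed=seed + 1000),
        )
        if len(query.peaks) > 8:
            query = query.copy(peaks=query.peaks[:8])
        a = align_peaks(query, ref)
        oracle_cos, oracle_n = _oracle_cosine(query, ref)
        assert a.n_matched == oracle_n
        assert cosine_score(a) == pytest.approx(oracle_cos, abs=1e-9)


class TestAgainstMatchms:
    def test_cosine_agrees_on_identical_alignment(self):
        """Independent cross-check of the cosine formula against
        matchms CosineGreedy on pairs whose peak pairing is
        unambiguous (deviations far inside or outside tolerance)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(21)
        for trial in range(10):
            ref = generate_reference_spectrum(280.0 + trial, 8, seed=trial + 40)
            query = corrupt_spectrum(
                ref, CorruptionConfig(ppm_jitter_sd=0.5, intensity_noise_cv=0.4,
                                      dropout_p=0.2, n_chimeric=3, seed=trial + 90),
            )
            ms_ref = matchms.Spectrum(
                mz=ref.mz, intensities=ref.intensity,
                metadata={"precursor_mz": ref.precursor_mz}, metadata_harmonization=False,
            )
            ms_q = matchms.Spectrum(
                mz=query.mz, intensities=query.intensity,
                metadata={"precursor_mz": query.precursor_mz}, metadata_harmonization=False,
            )
            # 5 ppm at <=300 m/z is < 0.0015 Da everywhere in range
            expected = CosineGreedy(tolerance=300.0 * 5e-6).pair(ms_q, ms_ref)
            ours = cosine_score(align_peaks(query, ref, fragment_tol_ppm=5.0))
            assert ours == pytest.approx(float(expected["score"]), abs=1e-6)


class TestMatchFeature:
    def _library(self):
        lib = SpectralLibrary()
        for i, energy in enumerate((10.0, 20.0, 40.0)):
            lib.append(
                generate_reference_spectrum(
                    320.0, 8 - i, seed=60 + i, compound_id="TARGET",
                    collision_energy=energy,
                )
            )
        lib.append(generate_reference_spectrum(450.0, 8, seed=70, compound_id="OTHER"))
        return lib

    def test_precursor_window_excludes_candidates(self):
        lib = self._library()
        off = 320.0 * (1 + 4e-6)  # 4 ppm away with 3 ppm tolerance
        query = _spectrum("q", [100.0], [1.0], off)
        assert match_feature(query, lib, PROFILES["in_silico"]) == []

    def test_best_energy_selected_and_reported(self):
        lib = self._library()
        target_20 = [s for s in lib if s.compound_id == "TARGET" and s.collision_energy == 20.0][0]
        query = target_20.copy(compound_id="q")
        hits = match_feature(query, lib, PROFILES["in_silico"])
        assert hits[0].reference_id == "TARGET"
        assert hits[0].collision_energy_used == 20.0
        assert hits[0].cosine == pytest.approx(1.0)

    def test_low_scores_dropped(self):
        lib = self._library()
        # same precursor, disjoint peaks -> cosine 0 < reporting floor
        query = _spectrum("q", [33.3, 44.4], [1.0, 1.0], 320.0)
        assert match_feature(query, lib, PROFILES["in_silico"]) == []

    def test_missing_precursor_errors(self):
        query = Spectrum("q", [Peak(50.0, 1.0)], 0.0, polarity="positive")
        with pytest.raises(ValueError):
            match_feature(query, self._library(), PROFILES["in_silico"])

    def test_ranking_deterministic_under_insertion_order(self):
        lib = self._library()
        shuffled = SpectralLibrary(reversed(list(lib)))
        query = [s for s in lib if s.collision_energy == 20.0][0].copy(compound_id="q")
        a = match_feature(query, lib, PROFILES["in_silico"])
        b = match_feature(query, shuffled, PROFILES["in_silico"])
        assert [(h.reference_id, h.cosine) for h in a] == [(h.reference_id, h.cosine) for h in b]


class TestDecide:
    def _scores(self, cosine, ei, nfrag=3):
        return MatchScores("REF", cosine, ei, nfrag, 20.0, "[M+H]+", "q")

    def test_in_silico_true_positive_regime(self):
        # low cosine, very high explained intensity: accepted under the
        # in-silico profile (0.2 / 0.7)
        d = decide(self._scores(0.247, 0.984), PROFILES["in_silico"])
        assert d.verdict == "accepted"

    def test_experimental_profile_rejects_below_consensus(self):
        d = decide(self._scores(0.65, 0.5), PROFILES["experimental"])
        assert d.verdict == "rejected"
        assert "min_cosine" in d.reasons and "min_explained_intensity" in d.reasons

    def test_perfect_match_accepted_everywhere(self):
        for profile in PROFILES.values():
            assert decide(self._scores(1.0, 1.0), profile).verdict == "accepted"

    def test_curation_when_only_cosine_fails(self):
        d = decide(self._scores(0.15, 0.95), PROFILES["in_silico"])
        assert d.verdict == "candidate_for_curation"
        assert d.reasons == ["min_cosine"]

    def test_fragment_minimum_enforced(self):
        d = decide(self._scores(0.9, 0.95, nfrag=1), PROFILES["in_silico"])
        assert d.verdict == "rejected"
        assert "min_matched_fragments" in d.reasons
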