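"""Modified cosine (against brute-force and matchms oracles), network
construction, spectral families and library search."""

import itertools

import numpy as np
import pytest

from nanorapids.network import (
    _candidate_pairs,
    build_network,
    library_search,
    modified_cosine,
    spectral_families,
)
from nanorapids.spectra import FragmentSpectrum


def brute_force_cosine(a, b, tol=0.9):
    """Independent oracle: exhaustive optimal one-to-one assignment."""
    pairs = _candidate_pairs(a, b, tol)
    best = 0.0

    def rec(idx, used_a, used_b, acc):
        nonlocal best
        best = max(best, acc)
        for k in range(idx, len(pairs)):
            s, i, j = pairs[k]
            if i not in used_a and j not in used_b:
                rec(k + 1, used_a | {i}, used_b | {j}, acc + s)

    rec(0, frozenset(), frozenset(), 0.0)
    norm = float(
        np.linalg.norm(np.sqrt(a.intensity)) * np.linalg.norm(np.sqrt(b.intensity))
    )
    return min(1.0, best / norm) if norm else 0.0


def _spec(prec, peaks, fid=None):
    return FragmentSpectrum(precursor_mz=prec, peaks=np.asarray(peaks),
                            feature_id=fid)


def random_spectrum(rng, n_peaks=None, fid=None):
    n = n_peaks or int(rng.integers(2, 9))
    peaks = np.column_stack(
        [np.sort(rng.uniform(100, 1000, n)), rng.uniform(1, 100, n)]
    )
    return _spec(float(rng.uniform(400, 1200)), peaks, fid)


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = _spec(500.0, [[100.0, 10.0], [200.0, 40.0], [300.0, 5.0]])
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0)
        assert matched == 3

    def test_disjoint_peaks_score_zero(self):
        a = _spec(500.0, [[100.0, 10.0], [200.0, 10.0]])
        b = _spec(500.0, [[150.0, 10.0], [250.0, 10.0]])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_shifted_peaks_match_through_precursor_delta(self):
        # b is a +14.01565 homolog whose fragments all shift with it
        a = _spec(500.0, [[150.0, 50.0], [260.0, 100.0]])
        b = _spec(514.01565, [[164.01565, 50.0], [274.01565, 100.0]])
        score, matched = modified_cosine(a, b)
        assert score == pytest.approx(1.0)
        assert matched == 2

    def test_empty_spectrum_scores_zero_without_error(self):
        a = _spec(500.0, [[100.0, 10.0]])
        b = FragmentSpectrum(precursor_mz=400.0, peaks=np.empty((0, 2)))
        assert modified_cosine(a, b) == (0.0, 0)

    def test_toy_pair_matches_exhaustive_oracle(self):
        a = _spec(400.0, [[110.0, 30.0], [210.0, 80.0], [350.0, 20.0]])
        b = _spec(414.0, [[110.2, 25.0], [224.0, 70.0], [363.8, 30.0]])
        greedy, _ = modified_cosine(a, b)
        assert greedy == pytest.approx(brute_force_cosine(a, b), abs=1e-12)

    def test_symmetry_and_bounds_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b = random_spectrum(rng), random_spectrum(rng)
            sab, mab = modified_cosine(a, b)
            sba, mba = modified_cosine(b, a)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert mab == mba
            assert 0.0 <= sab <= 1.0

    def test_greedy_equals_optimal_on_small_random_suite(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a, b = random_spectrum(rng), random_spectrum(rng)
            greedy, _ = modified_cosine(a, b)
            assert greedy == pytest.approx(brute_force_cosine(a, b), abs=1e-10)

    def test_agrees_with_matchms_reference(self):
        matchms = pytest.importorskip("matchms")
        from matchms import Spectrum
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(21)
        sim = ModifiedCosine(tolerance=0.9, intensity_power=0.5)
        for _ in range(25):
            a, b = random_spectrum(rng), random_spectrum(rng)
            ma = Spectrum(mz=a.mz, intensities=a.intensity,
                          metadata={"precursor_mz": a.precursor_mz},
                          metadata_harmonization=False)
            mb = Spectrum(mz=b.mz, intensities=b.intensity,
                          metadata={"precursor_mz": b.precursor_mz},
                          metadata_harmonization=False)
            ref = sim.pair(ma, mb)
            ours, _ = modified_cosine(a, b)
            assert ours == pytest.approx(float(ref["score"]), abs=1e-6)


class TestBuildNetwork:
    def _identical_triplet(self):
        peaks = [[100.0, 10.0], [200.0, 40.0], [300.0, 25.0], [380.0, 15.0]]
        return [_spec(500.0, peaks, fid=i) for i in (1, 2, 3)]

    def test_identical_spectra_form_triangle(self):
        g = build_network(self._identical_triplet())
        assert g.number_of_edges() == 3
        for _, _, d in g.edges(data=True):
            assert d["cosine"] == pytest.approx(1.0)

    def test_cosine_threshold_excludes_weak_pairs(self):
        # four shared minor peaks but disjoint base peaks: matched >= 4
        # yet cosine 0.67 — the edge must fall to the score filter
        shared = [[200.0, 50.0], [300.0, 50.0], [400.0, 50.0], [450.0, 50.0]]
        a = _spec(500.0, [[100.0, 100.0]] + shared, fid=1)
        b = _spec(500.0, [[120.0, 100.0]] + shared, fid=2)
        cos, matched = modified_cosine(a, b)
        assert matched >= 4 and cos < 0.7
        g = build_network([a, b])
        assert g.number_of_edges() == 0

    def test_min_matched_requires_more_than_three_peaks(self):
        # identical 3-peak spectra: cosine 1.0 but only 3 matched peaks
        peaks = [[100.0, 10.0], [200.0, 40.0], [300.0, 25.0]]
        specs = [_spec(500.0, peaks, fid=i) for i in (1, 2)]
        g = build_network(specs, min_matched=4)
        assert g.number_of_edges() == 0
        g2 = build_network(specs, min_matched=3)
        assert g2.number_of_edges() == 1

    def test_raising_thresholds_never_adds_edges(self):
        rng = np.random.default_rng(5)
        specs = [random_spectrum(rng, fid=i) for i in range(12)]
        base = set(build_network(specs, cosine_threshold=0.3,
                                 min_matched=2).edges())
        stricter = set(build_network(specs, cosine_threshold=0.5,
                                     min_matched=3).edges())
        assert stricter <= base

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        specs = [random_spectrum(rng, fid=i) for i in range(10)]
        g1 = build_network(specs, cosine_threshold=0.3, min_matched=2)
        rng.shuffle(specs)
        g2 = build_network(specs, cosine_threshold=0.3, min_matched=2)
        assert set(g1.edges()) == set(g2.edges())
        assert set(g1.nodes()) == set(g2.nodes())

    def test_no_self_loops(self):
        g = build_network(self._identical_triplet())
        assert all(u != v for u, v in g.edges())


class TestSpectralFamilies:
    def test_edgeless_network_is_all_singletons(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(5))
        fams, singles = spectral_families(g)
        assert fams == [] and singles == 5

    def test_triangle_plus_isolated(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from([1, 2, 3, 10, 11])
        g.add_edges_from([(1, 2), (2, 3), (1, 3)])
        fams, singles = spectral_families(g)
        assert fams == [[1, 2, 3]] and singles == 2

    def test_homolog_series_clusters_into_one_family(self):
        # CH2-spaced precursors sharing a fragment core: one family
        core = [[150.0, 60.0], [260.0, 100.0], [340.0, 40.0]]
        specs = []
        for k in range(4):
            prec = 1000.0 + k * 14.01565
            shifted = [[prec - 18.01, 80.0], [prec - 117.08, 30.0]]
            specs.append(_spec(prec, core + shifted, fid=k + 1))
        g = build_network(specs)
        fams, singles = spectral_families(g)
        assert len(fams) == 1 and sorted(fams[0]) == [1, 2, 3, 4]
        assert singles == 0


class TestLibrarySearch:
    def test_identical_entry_scores_one(self):
        peaks = [[100.0, 10.0], [200.0, 40.0], [300.0, 25.0]]
        q = _spec(500.0, peaks, fid=7)
        lib = [_spec(500.0, peaks), _spec(600.0, [[111.0, 5.0]])]
        lib[0].name = "compound X"
        hits = library_search([q], lib)
        assert hits[7].name == "compound X"
        assert hits[7].score == pytest.approx(1.0)
        assert hits[7].matched_peaks == 3

    def test_no_match_above_threshold_leaves_unannotated(self):
        q = _spec(500.0, [[100.0, 10.0], [200.0, 40.0]], fid=7)
        lib = [_spec(900.0, [[555.0, 10.0], [666.0, 10.0]])]
        assert library_search([q], lib) == {}

    def test_empty_library_rejected(self):
        q = _spec(500.0, [[100.0, 10.0]], fid=1)
        with pytest.raises(ValueError):
            library_search([q], [])

    def test_shuffled_decoys_rarely_reach_threshold(self):
        # shuffled-peak decoys must stay below the 0.7 score floor in
        # at least 95% of trials
        rng = np.random.default_rng(17)
        n_fail = 0
        trials = 100
        for _ in range(trials):
            q = random_spectrum(rng, n_peaks=8, fid=1)
            decoy_mz = np.sort(rng.uniform(100, 1000, 8))
            decoy = _spec(q.precursor_mz,
                          np.column_stack([decoy_mz,
                                           rng.permutation(q.intensity)]))
            score, matched = modified_cosine(q, decoy)
            if score > 0.7 and matched >= 3:
                n_fail += 1
        assert n_fail / trials <= 0.05
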