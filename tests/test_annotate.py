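import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import collinear_marker_hits, make_peak
from vocbin.annotate import (annotate_sample, candidate_bins, required_similarity,
                             resolve_isomers)
from vocbin.config import MatchConfig, ThresholdRule
from vocbin.models import Spectrum
from vocbin.registry import Bin
from vocbin.ri import fit_correction_curve, rt_to_ri
from vocbin.similarity import similarity

spectra = st.dictionaries(
    st.integers(35, 500), st.integers(1, 10**6), min_size=1, max_size=30
).map(lambda d: Spectrum(tuple(sorted(d.items()))))


def make_bin(bin_id, ri, quantifier=93, pairs=None, unique_masses=None):
    if pairs is None:
        merged = {41: 300, 121: 400}
        merged[quantifier] = 999
        pairs = list(merged.items())
    return Bin(
        bin_id=bin_id,
        spectrum=Spectrum(tuple(sorted(pairs))),
        ri=ri,
        quantifier_mass=quantifier,
        unique_masses=frozenset(unique_masses or {quantifier}),
    )


class TestSimilarity:
    def test_self_similarity_is_1000(self):
        s = Spectrum(((41, 100), (93, 500)))
        assert similarity(s, s) == 1000

    def test_proportional_spectra_score_1000(self):
        a = Spectrum(((41, 100), (93, 500)))
        b = Spectrum(((41, 200), (93, 1000)))
        assert similarity(a, b) == 1000

    def test_disjoint_spectra_score_0(self):
        assert similarity(Spectrum(((41, 100),)), Spectrum(((93, 100),))) == 0

    def test_hand_computed_example(self):
        # cos = sqrt(100)*sqrt(100) / (sqrt(100+100)*sqrt(100)) = 1/sqrt(2)
        a = Spectrum(((41, 100), (93, 100)))
        b = Spectrum(((93, 100),))
        assert similarity(a, b) == round(1000 / math.sqrt(2))

    @settings(max_examples=60, deadline=None)
    @given(spectra, spectra)
    def test_symmetric_and_bounded(self, a, b):
        assert similarity(a, b) == similarity(b, a)
        assert 0 <= similarity(a, b) <= 1000


class TestRequiredSimilarity:
    def test_pure_abundant_peak_needs_high_score(self):
        # the worked-example peak: purity 0.1137, strong signal
        assert required_similarity(sn=100.0, purity=0.1137) == 800

    def test_coeluting_small_peak_needs_least(self):
        assert required_similarity(sn=10.0, purity=2.0) == 600

    def test_intermediate_purity(self):
        assert required_similarity(sn=10.0, purity=0.5) == 700

    def test_threshold_monotone_in_purity(self):
        for sn in (5.0, 50.0, 500.0):
            assert required_similarity(sn, 0.1) >= required_similarity(sn, 2.0)

    def test_schedule_must_end_with_catch_all(self):
        with pytest.raises(ValueError):
            MatchConfig(threshold_schedule=[ThresholdRule(min_score=800, max_purity=0.5)])


class TestCandidateBins:
    def test_two_of_three_window_bins_share_the_unique_ion(self):
        """Three bins inside the RI window; only the two carrying the
        peak's unique ion m/z 93 survive the ion filter."""
        bins = [
            make_bin(1, 446700 - 1200, quantifier=93),
            make_bin(2, 446700 + 1200, quantifier=93),
            make_bin(3, 446700 + 500, quantifier=121),
        ]
        peak = make_peak([(41, 300), (93, 999)], unique_mass=93, apex_masses={93})
        cands = candidate_bins(peak, 446700.0, bins)
        assert {b.bin_id for b in cands} == {1, 2}

    def test_boundary_exclusive_beyond_window(self):
        bins = [make_bin(1, 446700 + 2000), make_bin(2, 446700 + 2001)]
        peak = make_peak([(93, 999)], unique_mass=93)
        assert [b.bin_id for b in candidate_bins(peak, 446700.0, bins)] == [1]

    def test_apex_mass_match_suffices(self):
        bins = [make_bin(1, 446700.0, quantifier=93)]
        peak = make_peak([(93, 500), (121, 999)], unique_mass=121,
                         apex_masses={121, 93})
        assert candidate_bins(peak, 446700.0, bins) == bins

    def test_ordered_by_ri_distance(self):
        bins = [make_bin(1, 446700 + 1500), make_bin(2, 446700 - 300)]
        peak = make_peak([(93, 999)], unique_mass=93)
        assert [b.bin_id for b in candidate_bins(peak, 446700.0, bins)] == [2, 1]


class TestResolveIsomers:
    def test_closest_ri_wins_without_significant_override(self):
        a, b = make_bin(1, 447000), make_bin(2, 447600)
        winner = resolve_isomers([(a, 850), (b, 860)], 446700.0)
        assert winner is a  # delta 10 < 50

    def test_significantly_better_similarity_overrides(self):
        a, b = make_bin(1, 447000), make_bin(2, 447600)
        winner = resolve_isomers([(a, 700), (b, 800)], 446700.0)
        assert winner is b  # delta 100 >= 50

    def test_ri_tie_broken_by_similarity(self):
        a, b = make_bin(1, 446700 + 300), make_bin(2, 446700 - 300)
        assert resolve_isomers([(a, 700), (b, 800)], 446700.0) is b

    def test_full_tie_broken_by_lower_bin_id(self):
        a, b = make_bin(1, 447000), make_bin(2, 447000)
        assert resolve_isomers([(a, 700), (b, 700)], 446700.0) is a


def brute_force_annotate(peaks, curve, bins, cfg):
    """Independent re-derivation of the greedy annotation outcome.

    Enumerates every (peak, bin) pair, applies the RI-window, ion and
    adaptive-similarity filters from their definitions (with its own cosine
    on the union grid), then replays the intensity-ordered claim rule.
    """
    def cosine(a, b):
        mzs = sorted(set(m for m, _ in a.peaks) | set(m for m, _ in b.peaks))
        va = np.sqrt([dict(a.peaks).get(m, 0) for m in mzs])
        vb = np.sqrt([dict(b.peaks).get(m, 0) for m in mzs])
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        return int(round(1000 * float(va @ vb) / denom)) if denom else 0

    def min_score(p):
        if p.purity < 0.15 and p.sn >= 50:
            return 800
        if p.purity < 1.5:
            return 700
        return 600

    eligible = {}
    for i, p in enumerate(peaks):
        ri = rt_to_ri(curve, p.rt)
        for b in bins:
            in_window = abs(b.ri - ri) <= cfg.ri_window
            ion_ok = p.unique_mass in b.unique_masses or bool(p.apex_masses & b.unique_masses)
            score = cosine(p.spectrum, b.spectrum)
            if in_window and ion_ok and score >= min_score(p):
                eligible[(i, b.bin_id)] = (score, abs(b.ri - ri))

    order = sorted(range(len(peaks)),
                   key=lambda i: (-peaks[i].unique_ion_height, peaks[i].rt, i))
    taken, assignment = set(), {}
    for i in order:
        cands = [(bid, s, d) for (pi, bid), (s, d) in eligible.items()
                 if pi == i and bid not in taken]
        if not cands:
            continue
        ri_win = min(cands, key=lambda c: (c[2], -c[1], c[0]))
        sim_win = max(cands, key=lambda c: (c[1], -c[2], -c[0]))
        chosen = sim_win if sim_win[1] - ri_win[1] >= cfg.isomer_delta else ri_win
        taken.add(chosen[0])
        assignment[i] = chosen[0]
    return assignment


def random_instance(rng, marker_table, n_bins=20, n_peaks=50):
    curve = fit_correction_curve(collinear_marker_hits(marker_table), marker_table)
    bins = []
    for bid in range(1, n_bins + 1):
        mzs = sorted(rng.choice(np.arange(35, 300), size=6, replace=False))
        pairs = tuple((int(m), int(rng.integers(100, 999))) for m in mzs)
        quant = int(pairs[int(rng.integers(0, len(pairs)))][0])
        bins.append(Bin(bin_id=bid, spectrum=Spectrum(pairs),
                        ri=float(rng.uniform(300_000, 950_000)),
                        quantifier_mass=quant, unique_masses=frozenset({quant})))
    peaks = []
    for _ in range(n_peaks):
        if rng.random() < 0.7:  # derived from a bin with perturbation
            b = bins[int(rng.integers(0, len(bins)))]
            pairs = {m: max(1, int(i * rng.uniform(0.6, 1.4))) for m, i in b.spectrum.peaks}
            if rng.random() < 0.3:
                pairs[int(rng.integers(35, 300))] = int(rng.integers(50, 999))
            ri = b.ri + float(rng.uniform(-2500, 2500))
            unique = b.quantifier_mass if rng.random() < 0.8 else int(rng.integers(35, 300))
            pairs.setdefault(unique, int(rng.integers(50, 999)))
            spectrum = Spectrum(tuple(sorted(pairs.items())))
        else:
            mzs = sorted(rng.choice(np.arange(35, 300), size=6, replace=False))
            spectrum = Spectrum(tuple((int(m), int(rng.integers(50, 999))) for m in mzs))
            unique = int(spectrum.peaks[0][0])
            ri = float(rng.uniform(300_000, 950_000))
        peaks.append(make_peak(list(spectrum.peaks), rt=ri / 1000.0,
                               unique_mass=unique,
                               apex_masses={unique},
                               sn=float(rng.uniform(5, 200)),
                               purity=float(rng.uniform(0.01, 3.0)),
                               height=float(rng.uniform(1_000, 100_000))))
    return peaks, curve, bins


class TestAnnotateSample:
    def test_single_peak_single_bin(self, collinear_curve):
        b = make_bin(1, 446700.0)
        peak = make_peak([(41, 300), (93, 999), (121, 400)], rt=446.7, unique_mass=93)
        anns, un = annotate_sample([peak], collinear_curve, [b])
        assert len(anns) == 1 and anns[0].bin_id == 1 and un == []
        assert anns[0].value == peak.unique_ion_height

    def test_coeluting_feedback_claims_both_bins(self, collinear_curve):
        """The stronger peak claims its best Bin; the weaker falls through."""
        a, b = make_bin(1, 446500.0), make_bin(2, 447000.0)
        strong = make_peak([(41, 300), (93, 999), (121, 400)], rt=446.5,
                           unique_mass=93, height=50_000)
        weak = make_peak([(41, 300), (93, 999), (121, 400)], rt=446.6,
                         unique_mass=93, height=10_000)
        anns, un = annotate_sample([strong, weak], collinear_curve, [a, b])
        assert {(a_.peak.unique_ion_height, a_.bin_id) for a_ in anns} == {
            (50_000, 1), (10_000, 2)
        }
        assert un == []

    def test_deterministic(self, marker_table):
        rng = np.random.default_rng(17)
        peaks, curve, bins = random_instance(rng, marker_table)
        first = annotate_sample(peaks, curve, bins)
        second = annotate_sample(peaks, curve, bins)
        assert first == second

    def test_widening_window_never_loses_annotations(self, marker_table):
        rng = np.random.default_rng(23)
        peaks, curve, bins = random_instance(rng, marker_table)
        narrow, _ = annotate_sample(peaks, curve, bins, MatchConfig(ri_window=1000))
        wide, _ = annotate_sample(peaks, curve, bins, MatchConfig(ri_window=4000))
        assert len(wide) >= len(narrow)

    def test_lowering_thresholds_never_loses_annotations(self, marker_table):
        rng = np.random.default_rng(29)
        peaks, curve, bins = random_instance(rng, marker_table)
        strict, _ = annotate_sample(peaks, curve, bins)
        lax_cfg = MatchConfig(threshold_schedule=[ThresholdRule(min_score=300)])
        lax, _ = annotate_sample(peaks, curve, bins, lax_cfg)
        assert len(lax) >= len(strict)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, marker_table):
        rng = np.random.default_rng(100 + seed)
        peaks, curve, bins = random_instance(rng, marker_table)
        cfg = MatchConfig()
        anns, _ = annotate_sample(peaks, curve, bins, cfg)
        ours = {id(a.peak): a.bin_id for a in anns}
        index = {id(p): i for i, p in enumerate(peaks)}
        ours_by_index = {index[k]: v for k, v in ours.items()}
        assert ours_by_index == brute_force_annotate(peaks, curve, bins, cfg)
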