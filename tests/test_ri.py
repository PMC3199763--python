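import datetime as dt

import numpy as np
import pytest

from conftest import collinear_marker_hits, make_peak
from vocbin.config import MarkerConfig
from vocbin.errors import (CurveFitError, RiRangeError, UnprocessableSampleError)
from vocbin.ri import (FAME_C4_KOVATS, FAME_C4_RI, FAME_C24_KOVATS, FAME_C24_RI,
                       MarkerHit, fit_correction_curve, fit_partial_curve,
                       locate_fame_markers, resolve_fallback_curve, ri_to_rt,
                       rt_to_ri)
from vocbin.similarity import similarity
from vocbin.simulate import FixtureConfig, generate_experiment
from vocbin.io_formats import read_peak_table


class TestMarkerTable:
    def test_anchor_constants(self, marker_table):
        by_carbon = {m.carbon: m for m in marker_table}
        assert by_carbon[4].ri_fame == FAME_C4_RI == 262214
        assert by_carbon[24].ri_fame == FAME_C24_RI == 980934
        assert by_carbon[4].ri_alkane == FAME_C4_KOVATS == 726
        assert by_carbon[24].ri_alkane == FAME_C24_KOVATS == 2712

    def test_ri_strictly_increasing_with_carbon(self, marker_table):
        ris = [m.ri_fame for m in sorted(marker_table, key=lambda m: m.carbon)]
        assert all(b > a for a, b in zip(ris, ris[1:]))


def drifted_hits(markers, drift):
    """Marker hits at rt = nominal + drift(nominal)."""
    hits = []
    for m in markers:
        rt = m.nominal_rt + drift(m.nominal_rt)
        peak = make_peak(list(m.reference_spectrum.peaks), rt=rt, unique_mass=74)
        hits.append(MarkerHit(marker=m, peak=peak, similarity=1000))
    return hits


class TestCurveFit:
    def test_collinear_markers_reproduce_all_nominal_ris_exactly(
        self, collinear_curve, marker_table
    ):
        for m in marker_table:
            assert rt_to_ri(collinear_curve, m.ri_fame / 1000.0) == pytest.approx(
                m.ri_fame, abs=1e-6
            )

    def test_c4_marker_rt_maps_to_anchor(self, collinear_curve):
        assert rt_to_ri(collinear_curve, FAME_C4_RI / 1000.0) == pytest.approx(262214)

    def test_c24_marker_rt_maps_to_anchor(self, collinear_curve):
        assert rt_to_ri(collinear_curve, FAME_C24_RI / 1000.0) == pytest.approx(980934)

    def test_midpoint_of_collinear_markers_is_mean_ri(self, collinear_curve, marker_table):
        m = sorted(marker_table, key=lambda x: x.carbon)
        rt_mid = (m[4].ri_fame + m[5].ri_fame) / 2000.0
        expected = (m[4].ri_fame + m[5].ri_fame) / 2.0
        assert rt_to_ri(collinear_curve, rt_mid) == pytest.approx(expected, abs=1e-6)

    def test_mid_residuals_match_normal_equations_oracle(self, marker_table):
        """Least-squares check against an independent normal-equations solve.

        A sinusoidal drift is not in the quintic's column space, so the
        residuals are genuinely non-zero.
        """
        curve = fit_correction_curve(
            drifted_hits(marker_table, lambda t: 3.0 * np.sin(t / 120.0)), marker_table
        )
        hits = sorted(curve.marker_hits, key=lambda h: h.marker.carbon)
        rt = np.array([h.peak.rt for h in hits])[1:-1]  # the mid fit set
        ri = np.array([h.marker.ri_fame for h in hits])[1:-1]
        # oracle: explicit normal equations on the same centred design
        u = (rt - rt.mean()) / rt.std()
        A = np.vander(u, 6)
        coef = np.linalg.solve(A.T @ A, A.T @ ri)
        oracle_resid = (ri - A @ coef)[1:-1]  # inner markers, mid evaluation region
        ours = np.array([rt_to_ri(curve, float(t)) for t in rt[1:-1]])
        impl_resid = ri[1:-1] - ours
        assert np.abs(oracle_resid).max() > 1.0  # oracle sees real residuals
        assert np.linalg.norm(impl_resid - oracle_resid) <= 1e-6 * np.linalg.norm(oracle_resid)

    def test_incomplete_marker_set_rejected(self, marker_table):
        hits = collinear_marker_hits(marker_table)[:-1]
        with pytest.raises(CurveFitError):
            fit_correction_curve(hits, marker_table)

    def test_non_monotone_markers_rejected(self, marker_table):
        hits = collinear_marker_hits(marker_table)
        swapped = hits[:5] + [
            MarkerHit(hits[6].marker, hits[5].peak, 1000),
            MarkerHit(hits[5].marker, hits[6].peak, 1000),
        ] + hits[7:]
        with pytest.raises(CurveFitError):
            fit_correction_curve(swapped, marker_table)

    def test_linear_extrapolation_beyond_span(self, collinear_curve):
        # beyond C24 the tail line continues: exactly linear on this fixture
        assert rt_to_ri(collinear_curve, 1100.0) == pytest.approx(1_100_000.0)
        assert rt_to_ri(collinear_curve, 200.0) == pytest.approx(200_000.0)


class TestRtRiRoundTrip:
    def test_strictly_increasing_over_span(self, collinear_curve):
        rng = np.random.default_rng(5)
        rts = np.sort(rng.uniform(*collinear_curve.span, size=1000))
        ris = [rt_to_ri(collinear_curve, float(t)) for t in rts]
        assert all(b > a for a, b in zip(ris, ris[1:]))

    def test_round_trip_within_one_ri_unit(self, marker_table):
        curve = fit_correction_curve(
            drifted_hits(marker_table, lambda t: 3.0 * ((t - 100.0) / 800.0) ** 2),
            marker_table,
        )
        rng = np.random.default_rng(6)
        lo, hi = rt_to_ri(curve, curve.span[0]), rt_to_ri(curve, curve.span[1])
        for x in rng.uniform(lo, hi, size=1000):
            assert abs(rt_to_ri(curve, ri_to_rt(curve, float(x))) - x) <= 1.0

    def test_anchor_ri_inverts_to_marker_rt(self, collinear_curve):
        assert ri_to_rt(collinear_curve, 262214.0) == pytest.approx(262.214, abs=1e-6)

    def test_mid_segment_inverse_matches_bisection_oracle(self, marker_table):
        curve = fit_correction_curve(
            drifted_hits(marker_table, lambda t: 2e-6 * (t - 500.0) ** 2), marker_table
        )
        target = 600_000.0
        lo, hi = curve.boundaries
        for _ in range(60):  # plain bisection on the monotone mid segment
            mid = (lo + hi) / 2.0
            if rt_to_ri(curve, mid) < target:
                lo = mid
            else:
                hi = mid
        assert ri_to_rt(curve, target) == pytest.approx((lo + hi) / 2.0, abs=1e-3)

    def test_far_out_of_range_rejected(self, collinear_curve):
        with pytest.raises(RiRangeError):
            ri_to_rt(collinear_curve, 5_000_000.0)


@pytest.fixture(scope="module")
def sample_peaks(tmp_path_factory):
    out = tmp_path_factory.mktemp("loc")
    cfg = FixtureConfig(seed=3, n_classes=1, samples_per_class=1, n_decoys=200)
    _, tables, truth = generate_experiment(cfg, out, write_raw=False)
    sid = next(iter(tables))
    return read_peak_table(tables[sid], sample_id=sid).peaks, truth, sid


class TestLocateMarkers:
    def test_all_twelve_found_in_carbon_order(self, sample_peaks, marker_table):
        peaks, truth, sid = sample_peaks
        hits = locate_fame_markers(peaks, marker_table)
        assert [h.marker.carbon for h in hits] == [4, 6, 8, 9, 10, 12, 14, 16, 18, 20, 22, 24]
        for h in hits:  # assignment matches the generator's ground-truth RTs
            # the peak table stores rt at millisecond precision
            assert h.peak.rt == pytest.approx(truth.marker_rts[sid][h.marker.carbon], abs=2e-3)

    def test_removed_marker_yields_partial_hit_list(self, sample_peaks, marker_table):
        peaks, truth, sid = sample_peaks
        c24_rt = truth.marker_rts[sid][24]
        remaining = [p for p in peaks if abs(p.rt - c24_rt) > 0.01]
        hits = locate_fame_markers(remaining, marker_table)
        assert len(hits) == 11 and 24 not in {h.marker.carbon for h in hits}

    def test_dissimilar_base_peak_74_decoy_not_assigned(self, marker_table):
        cfg = MarkerConfig()
        markers = sorted(marker_table, key=lambda m: m.carbon)
        hits_clean = collinear_marker_hits(marker_table)
        c12 = next(m for m in markers if m.carbon == 12)
        # decoy sits exactly in the C12 slot but shares only m/z 74
        decoy = make_peak([(74, 999), (203, 500), (281, 400)],
                          rt=c12.ri_fame / 1000.0 + 1.0, unique_mass=74)
        assert similarity(decoy.spectrum, c12.reference_spectrum) < cfg.min_similarity
        peaks = [h.peak for h in hits_clean if h.marker.carbon != 12] + [decoy]
        hits = locate_fame_markers(peaks, marker_table, cfg)
        assert 12 not in {h.marker.carbon for h in hits}
        assert all(h.peak is not decoy for h in hits)

    def test_no_candidates_gives_empty_list(self, marker_table):
        peaks = [make_peak([(93, 999), (41, 300)], rt=float(r)) for r in (100, 200)]
        assert locate_fame_markers(peaks, marker_table) == []


class TestFallbackLadder:
    def _own(self, marker_table):
        return fit_correction_curve(collinear_marker_hits(marker_table), marker_table)

    def test_same_day_borrow(self, marker_table):
        own = self._own(marker_table)
        d = dt.date(2011, 3, 5)
        curve = resolve_fallback_curve(
            "bad", d, {"good": (d, own)}, hits=[], cfg=MarkerConfig()
        )
        assert curve.provenance.kind == "BORROWED"
        assert curve.provenance.day_offset == 0
        assert curve.provenance.source_sample_id == "good"
        assert not curve.bin_generation_allowed

    def test_within_ten_days_borrow(self, marker_table):
        own = self._own(marker_table)
        curve = resolve_fallback_curve(
            "bad", dt.date(2011, 3, 15), {"good": (dt.date(2011, 3, 5), own)},
            hits=[], cfg=MarkerConfig(),
        )
        assert curve.provenance.kind == "BORROWED" and curve.provenance.day_offset == 10
        assert not curve.bin_generation_allowed

    def test_beyond_ten_days_falls_to_partial(self, marker_table):
        own = self._own(marker_table)
        hits = collinear_marker_hits(marker_table)[3:8]  # 5 local markers survive
        curve = resolve_fallback_curve(
            "bad", dt.date(2011, 3, 20), {"good": (dt.date(2011, 3, 9), own)},
            hits=hits, cfg=MarkerConfig(),
        )
        assert curve.provenance.kind == "PARTIAL"
        assert not curve.bin_generation_allowed
        # partial curve interpolates its own markers exactly
        h = hits[2]
        assert rt_to_ri(curve, h.peak.rt) == pytest.approx(h.marker.ri_fame)

    def test_exhausted_ladder_raises(self, marker_table):
        one_hit = collinear_marker_hits(marker_table)[:1]
        with pytest.raises(UnprocessableSampleError):
            resolve_fallback_curve("bad", dt.date(2011, 3, 20), {}, hits=one_hit,
                                   cfg=MarkerConfig())

    def test_partial_needs_two_hits(self, marker_table):
        with pytest.raises(CurveFitError):
            fit_partial_curve(collinear_marker_hits(marker_table)[:1])


class TestDriftRecovery:
    @pytest.mark.parametrize("model", ["linear", "polynomial", "jitter"])
    def test_ri_spread_within_matching_window(self, model, tmp_path, marker_table):
        """3 s drifts leave per-compound RI spread far below the +/-2000 window."""
        cfg = FixtureConfig(seed=4, n_classes=1, samples_per_class=4,
                            drift_model=model, dropout_rate=0.0, n_decoys=0)
        _, tables, truth = generate_experiment(cfg, tmp_path / model, write_raw=False)
        observed: dict[str, list[float]] = {}
        for sid, path in tables.items():
            peaks = read_peak_table(path, sample_id=sid).peaks
            hits = locate_fame_markers(peaks, marker_table)
            curve = fit_correction_curve(hits, marker_table)
            for o in truth.occurrences:
                if o.sample_id == sid:
                    observed.setdefault(o.compound, []).append(rt_to_ri(curve, o.rt))
        for compound, ris in observed.items():
            assert max(ris) - min(ris) <= 2000.0, compound
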