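"""Retention-index correction from FAME markers.

Every sample is spiked with a C4-C24 fatty acid methyl ester (FAME)
series.  The markers are located without any retention-time prior: a base
peak filter (m/z 74/87, the characteristic FAME fragments) shortlists
candidates, the best spectral match anchors the series, and the remaining
markers are assigned walking outward using expected inter-marker RT
offsets.  The correction curve maps RT to FAME RI units with a linear
segment over the first two and last two markers, a fifth-order polynomial
over the middle eight, and linear extrapolation beyond the marker span.

When markers are missing, a fallback ladder borrows the curve of a
neighbouring sample (same day, then up to ten days away) or fits a
partial piecewise-linear curve from whatever markers were found; in all
fallback branches the sample may still be matched against existing Bins
but can no longer seed new ones.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .config import MarkerConfig
from .errors import CurveFitError, RiRangeError, UnprocessableSampleError
from .models import DeconvolutedPeak, Spectrum
from .similarity import similarity

# FAME RI anchor constants (FAME RI units)
FAME_C4_RI = 262_214.0
FAME_C24_RI = 980_934.0
# Kovats (alkane) equivalents of the two anchors
FAME_C4_KOVATS = 726.0
FAME_C24_KOVATS = 2712.0

MARKER_CARBONS = (4, 6, 8, 9, 10, 12, 14, 16, 18, 20, 22, 24)

# Nominal marker elution times (s) under the default temperature program;
# instrument-configuration data, used only for inter-marker offsets and by
# the synthetic-fixture generator, never as an absolute RT prior.
DEFAULT_MARKER_RT = {
    4: 120.0, 6: 180.0, 8: 260.0, 9: 300.0, 10: 340.0, 12: 420.0,
    14: 500.0, 16: 580.0, 18: 660.0, 20: 740.0, 22: 820.0, 24: 900.0,
}


@dataclass(frozen=True)
class MarkerDef:
    carbon: int
    ri_fame: float
    reference_spectrum: Spectrum
    ri_alkane: float | None = None
    base_peak_candidates: frozenset[int] = frozenset({74, 87})
    nominal_rt: float = 0.0  # instrument-config elution time (s)


@dataclass(frozen=True)
class MarkerHit:
    marker: MarkerDef
    peak: DeconvolutedPeak
    similarity: int


@dataclass(frozen=True)
class Provenance:
    kind: str  # OWN | BORROWED | PARTIAL
    source_sample_id: str | None = None
    day_offset: int = 0


@dataclass
class CorrectionCurve:
    """Piecewise RT -> FAME RI map.

    ``kind`` is "full" (two linear end segments + degree-5 middle) or
    "partial" (piecewise linear through the markers that were found).
    """

    kind: str
    provenance: Provenance
    bin_generation_allowed: bool
    marker_hits: list[MarkerHit] = field(default_factory=list)
    # full curve
    head: tuple[float, float] | None = None  # (slope, intercept)
    tail: tuple[float, float] | None = None
    mid: np.ndarray | None = None  # degree-5 coefficients in scaled rt
    mid_center: float = 0.0  # mid evaluated at u = (rt - center) / scale
    mid_scale: float = 1.0
    boundaries: tuple[float, float] | None = None  # rt of markers 2 and 11
    # partial curve
    knots_rt: np.ndarray | None = None
    knots_ri: np.ndarray | None = None
    span: tuple[float, float] = (0.0, 0.0)  # rt of first/last own marker
    warnings: list[str] = field(default_factory=list)


def fame_reference_spectrum(carbon: int) -> Spectrum:
    """Idealised EI spectrum of a saturated fatty acid methyl ester.

    The McLafferty rearrangement ion m/z 74 dominates, with m/z 87 and the
    acylium/molecular-ion region fragments (M-43, M) making chains
    distinguishable.  Synthetic reference patterns, not measured spectra.
    """
    mw = 14 * carbon + 46  # methyl ester of a Cn acid
    peaks = {43: 350, 55: 250, 74: 999, 87: 700}
    if 35 <= mw - 43 <= 500:
        peaks[mw - 43] = 150
    if 35 <= mw <= 500:
        peaks[mw] = 80
    return Spectrum(tuple(sorted(peaks.items())))


def default_marker_table() -> list[MarkerDef]:
    """The C4-C24 FAME marker series with its FAME RI grid.

    Only the C4 and C24 FAME RI values (262,214 and 980,934) and their
    Kovats equivalents (726 and 2712) are authoritative anchors; the
    intermediate values interpolate linearly in chain length and are
    placeholders to be overridden from an instrument marker file.
    """
    markers = []
    for c in MARKER_CARBONS:
        frac = (c - 4) / 20.0
        markers.append(
            MarkerDef(
                carbon=c,
                ri_fame=FAME_C4_RI + (FAME_C24_RI - FAME_C4_RI) * frac,
                ri_alkane=FAME_C4_KOVATS + (FAME_C24_KOVATS - FAME_C4_KOVATS) * frac,
                reference_spectrum=fame_reference_spectrum(c),
                nominal_rt=DEFAULT_MARKER_RT[c],
            )
        )
    return markers


# ---------------------------------------------------------------------------
# Marker location
# ---------------------------------------------------------------------------

def locate_fame_markers(
    peaks: list[DeconvolutedPeak],
    markers: list[MarkerDef] | None = None,
    cfg: MarkerConfig | None = None,
) -> list[MarkerHit]:
    """Find the FAME markers among all peaks of one sample.

    No retention-time prior is used for the anchor: candidates are peaks
    whose base peak is a FAME fragment, and the candidate/marker pair with
    the highest spectral similarity fixes the anchor identity.  The other
    markers are then assigned walking outward in RT using expected
    inter-marker offsets, each hit gated by ``cfg.min_similarity``.
    Returns hits sorted by carbon; may be partial or empty.
    """
    cfg = cfg or MarkerConfig()
    markers = sorted(markers or default_marker_table(), key=lambda m: m.carbon)
    bp_set = set(cfg.base_peak_candidates)
    candidates = [p for p in peaks if p.spectrum.base_peak_mz in bp_set]
    if not candidates:
        return []

    # anchor: globally best (candidate, marker) similarity
    best: tuple[int, int, int] | None = None  # (sim, cand idx, marker idx)
    for ci, cand in enumerate(candidates):
        for mi, m in enumerate(markers):
            s = similarity(cand.spectrum, m.reference_spectrum)
            if best is None or s > best[0]:
                best = (s, ci, mi)
    assert best is not None
    if best[0] < cfg.min_similarity:
        return []
    anchor_sim, anchor_ci, anchor_mi = best
    assigned: dict[int, tuple[DeconvolutedPeak, int]] = {
        anchor_mi: (candidates[anchor_ci], anchor_sim)
    }
    used = {anchor_ci}

    def try_assign(mi: int, ref_mi: int) -> None:
        ref_peak, _ = assigned[ref_mi]
        expected = ref_peak.rt + (markers[mi].nominal_rt - markers[ref_mi].nominal_rt)
        best_local: tuple[int, int] | None = None  # (sim, cand idx)
        for ci, cand in enumerate(candidates):
            if ci in used or abs(cand.rt - expected) > cfg.offset_tol:
                continue
            s = similarity(cand.spectrum, markers[mi].reference_spectrum)
            if s >= cfg.min_similarity and (best_local is None or s > best_local[0]):
                best_local = (s, ci)
        if best_local is not None:
            assigned[mi] = (candidates[best_local[1]], best_local[0])
            used.add(best_local[1])

    # walk outward from the anchor, each step referenced to the nearest
    # already-assigned marker so slow drifts accumulate correctly
    for mi in range(anchor_mi + 1, len(markers)):
        ref = max(i for i in assigned if i < mi)
        try_assign(mi, ref)
    for mi in range(anchor_mi - 1, -1, -1):
        ref = min(i for i in assigned if i > mi)
        try_assign(mi, ref)

    hits = [
        MarkerHit(marker=markers[mi], peak=pk, similarity=sim)
        for mi, (pk, sim) in sorted(assigned.items())
    ]
    return hits


# ---------------------------------------------------------------------------
# Curve fitting and evaluation
# ---------------------------------------------------------------------------

def _line_through(p1: tuple[float, float], p2: tuple[float, float]) -> tuple[float, float]:
    slope = (p2[1] - p1[1]) / (p2[0] - p1[0])
    return slope, p1[1] - slope * p1[0]


def fit_correction_curve(
    hits: list[MarkerHit],
    markers: list[MarkerDef] | None = None,
    cfg: MarkerConfig | None = None,
) -> CorrectionCurve:
    """Fit the full piecewise curve; requires all markers present.

    Head and tail lines pass exactly through their two markers; the middle
    segment is a least-squares degree-5 polynomial.  Its fit includes the
    boundary markers (2nd and 11th) alongside the middle eight so that the
    polynomial only ever interpolates inside its evaluation region —
    high-degree polynomials amplify marker RT noise severely when pushed
    even one inter-marker gap beyond their fit span.  The fitted map must
    be strictly increasing over the marker span or a
    :class:`CurveFitError` is raised (the caller then falls back).
    """
    cfg = cfg or MarkerConfig()
    markers = sorted(markers or default_marker_table(), key=lambda m: m.carbon)
    if len(hits) < len(markers):
        raise CurveFitError(f"only {len(hits)}/{len(markers)} markers found")
    hits = sorted(hits, key=lambda h: h.marker.carbon)
    rt = np.array([h.peak.rt for h in hits])
    ri = np.array([h.marker.ri_fame for h in hits])
    if np.any(np.diff(rt) <= 0):
        raise CurveFitError("marker RTs are not strictly increasing")
    head = _line_through((rt[0], ri[0]), (rt[1], ri[1]))
    tail = _line_through((rt[-2], ri[-2]), (rt[-1], ri[-1]))
    # fit in centred/scaled rt: the raw degree-5 Vandermonde over rts of
    # hundreds of seconds is catastrophically ill-conditioned
    center = float(rt[1:-1].mean())
    scale = float(rt[1:-1].std())
    mid = np.polyfit((rt[1:-1] - center) / scale, ri[1:-1], 5)
    curve = CorrectionCurve(
        kind="full",
        provenance=Provenance("OWN"),
        bin_generation_allowed=True,
        marker_hits=list(hits),
        head=head,
        tail=tail,
        mid=mid,
        mid_center=center,
        mid_scale=scale,
        boundaries=(float(rt[1]), float(rt[-2])),
        span=(float(rt[0]), float(rt[-1])),
    )
    # monotonicity is required within each evaluation segment; the segment
    # joins may carry small steps (noise in the marker RTs), which are
    # tolerated up to cfg.max_join_discontinuity and flagged beyond a tenth
    # of it, but a downward step past the tolerance fails the fit
    if head[0] <= 0 or tail[0] <= 0:
        raise CurveFitError("linear end segment is not increasing")
    grid = np.linspace(rt[1], rt[-2], 2001)
    if np.any(np.diff(np.polyval(mid, (grid - center) / scale)) <= 0):
        raise CurveFitError("middle polynomial is not strictly increasing over its span")
    for name, seg_lin, b in (("head/mid", head, rt[1]), ("mid/tail", tail, rt[-2])):
        lin_val = seg_lin[0] * b + seg_lin[1]
        mid_val = float(np.polyval(mid, (b - center) / scale))
        jump = mid_val - lin_val if name == "head/mid" else lin_val - mid_val
        if -jump > cfg.max_join_discontinuity:
            raise CurveFitError(
                f"{name} join decreases by {-jump:.0f} RI units at rt {b:.1f}"
            )
        if abs(jump) > cfg.max_join_discontinuity / 10:
            curve.warnings.append(
                f"{name} join discontinuity {jump:.0f} RI units at rt {b:.1f}"
            )
    return curve


def fit_partial_curve(hits: list[MarkerHit]) -> CorrectionCurve:
    """Piecewise-linear curve through >= 2 found markers (fallback only)."""
    if len(hits) < 2:
        raise CurveFitError("partial curve needs at least two marker hits")
    hits = sorted(hits, key=lambda h: h.marker.carbon)
    rt = np.array([h.peak.rt for h in hits])
    ri = np.array([h.marker.ri_fame for h in hits])
    if np.any(np.diff(rt) <= 0):
        raise CurveFitError("marker RTs are not strictly increasing")
    return CorrectionCurve(
        kind="partial",
        provenance=Provenance("PARTIAL"),
        bin_generation_allowed=False,
        marker_hits=list(hits),
        knots_rt=rt,
        knots_ri=ri,
        span=(float(rt[0]), float(rt[-1])),
    )


def _eval_curve(curve: CorrectionCurve, rt: np.ndarray) -> np.ndarray:
    rt = np.asarray(rt, dtype=float)
    if curve.kind == "full":
        b1, b2 = curve.boundaries  # type: ignore[misc]
        hs, hi = curve.head  # type: ignore[misc]
        ts, ti = curve.tail  # type: ignore[misc]
        u = (rt - curve.mid_center) / curve.mid_scale
        out = np.where(
            rt <= b1, hs * rt + hi,
            np.where(rt >= b2, ts * rt + ti, np.polyval(curve.mid, u)),
        )
        return out
    # partial: piecewise linear with end-slope extrapolation
    k_rt, k_ri = curve.knots_rt, curve.knots_ri  # type: ignore[assignment]
    out = np.interp(rt, k_rt, k_ri)
    lo_slope = (k_ri[1] - k_ri[0]) / (k_rt[1] - k_rt[0])
    hi_slope = (k_ri[-1] - k_ri[-2]) / (k_rt[-1] - k_rt[-2])
    out = np.where(rt < k_rt[0], k_ri[0] + lo_slope * (rt - k_rt[0]), out)
    out = np.where(rt > k_rt[-1], k_ri[-1] + hi_slope * (rt - k_rt[-1]), out)
    return out


def rt_to_ri(curve: CorrectionCurve, rt: float) -> float:
    """Map a retention time (s) to FAME RI units (linear beyond the span)."""
    return float(_eval_curve(curve, np.array([rt]))[0])


def ri_to_rt(curve: CorrectionCurve, ri: float, cfg: MarkerConfig | None = None) -> float:
    """Invert the correction curve on its monotone span.

    Raises :class:`RiRangeError` for indices more than
    ``cfg.extrapolation_cap`` RI units beyond the calibrated span.
    """
    cfg = cfg or MarkerConfig()
    lo, hi = curve.span
    ri_lo, ri_hi = rt_to_ri(curve, lo), rt_to_ri(curve, hi)
    if ri < ri_lo - cfg.extrapolation_cap or ri > ri_hi + cfg.extrapolation_cap:
        raise RiRangeError(f"RI {ri:.0f} beyond calibrated+extrapolated range")
    # expand bracket into the linear extrapolation region if needed
    rt_lo, rt_hi = lo, hi
    step = max((hi - lo) * 0.05, 1.0)
    while rt_to_ri(curve, rt_lo) > ri:
        rt_lo -= step
        step *= 2
    step = max((hi - lo) * 0.05, 1.0)
    while rt_to_ri(curve, rt_hi) < ri:
        rt_hi += step
        step *= 2
    return float(brentq(lambda t: rt_to_ri(curve, t) - ri, rt_lo, rt_hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# Fallback ladder
# ---------------------------------------------------------------------------

def resolve_fallback_curve(
    sample_id: str,
    date: _dt.date | None,
    curves_by_sample: dict[str, tuple[_dt.date, CorrectionCurve]],
    hits: list[MarkerHit],
    cfg: MarkerConfig | None = None,
) -> CorrectionCurve:
    """Obtain a curve for a sample whose own marker fit failed.

    Preference order: a same-day neighbour's OWN curve, then the nearest
    OWN curve within ``cfg.borrow_max_days``, then a partial curve through
    whatever markers were found.  Bin generation is disabled in every
    branch.  Raises :class:`UnprocessableSampleError` when all branches
    are exhausted.
    """
    cfg = cfg or MarkerConfig()
    own = [
        (abs((d - date).days), d, sid, curve)
        for sid, (d, curve) in curves_by_sample.items()
        if sid != sample_id and curve.provenance.kind == "OWN" and date is not None
    ]
    own.sort(key=lambda t: (t[0], t[2]))
    if own and own[0][0] == 0:
        delta, _, src, curve = own[0]
        return replace(
            curve,
            provenance=Provenance("BORROWED", source_sample_id=src, day_offset=0),
            bin_generation_allowed=False,
        )
    if own and own[0][0] <= cfg.borrow_max_days:
        delta, _, src, curve = own[0]
        return replace(
            curve,
            provenance=Provenance("BORROWED", source_sample_id=src, day_offset=delta),
            bin_generation_allowed=False,
        )
    if len(hits) >= 2:
        return fit_partial_curve(hits)
    raise UnprocessableSampleError(
        f"sample {sample_id}: no borrowable curve and {len(hits)} marker hit(s)"
    )
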