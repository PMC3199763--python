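"""Multi-tiered annotation of deconvoluted peaks against the Bin list.

Peaks are processed in order of decreasing unique-ion height.  For each
peak the engine (1) restricts candidates to Bins within an RI window of
±2000 FAME RI units, (2) requires the peak's unique ion or one of its
apex ions to appear in the Bin's unique-mass list, (3) applies a
spectral-similarity gate whose threshold adapts to peak signal-to-noise
and purity (clean, abundant peaks must match better than small or
co-eluting ones), and (4) resolves remaining stereoisomer-style
ambiguity in favour of the closest RI unless another candidate scores
significantly higher.  A Bin claimed within a sample is withdrawn from
the candidate sets of later (weaker) peaks, so peaks losing an isomer
contest fall through to their next-best neighbouring Bin.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import MatchConfig, ThresholdRule
from .models import DeconvolutedPeak
from .registry import Bin
from .ri import CorrectionCurve, rt_to_ri
from .similarity import similarity

PASS_FIRST = "FIRST"
PASS_POST = "POST"
PASS_REPLACED = "REPLACED"


@dataclass(frozen=True)
class Annotation:
    peak: DeconvolutedPeak | None
    bin_id: int
    sample_id: str
    similarity: int | None
    ri_observed: float | None
    pass_: str  # FIRST | POST | REPLACED
    value: float  # quantifier-mass height (or replacement intensity)

    def __post_init__(self) -> None:
        if self.pass_ == PASS_REPLACED and self.similarity is not None:
            raise ValueError("replacement annotations carry no similarity score")


def required_similarity(
    sn: float, purity: float, schedule: list[ThresholdRule] | None = None
) -> int:
    """Adaptive minimum similarity: first matching schedule rule wins."""
    schedule = schedule or MatchConfig().threshold_schedule
    for rule in schedule:
        if rule.matches(sn, purity):
            return rule.min_score
    return schedule[-1].min_score


def candidate_bins(
    peak: DeconvolutedPeak,
    ri: float,
    bins: list[Bin],
    cfg: MatchConfig | None = None,
) -> list[Bin]:
    """RI-window plus unique/apex-ion filter; ordered by |ΔRI| then id."""
    cfg = cfg or MatchConfig()
    out = [
        b for b in bins
        if abs(b.ri - ri) <= cfg.ri_window
        and (peak.unique_mass in b.unique_masses or peak.apex_masses & b.unique_masses)
    ]
    out.sort(key=lambda b: (abs(b.ri - ri), b.bin_id))
    return out


def resolve_isomers(
    candidates: list[tuple[Bin, int]],
    ri: float,
    cfg: MatchConfig | None = None,
) -> Bin:
    """Closest-RI rule with a similarity override.

    The candidate nearest in RI wins unless another candidate's similarity
    exceeds the RI winner's by at least ``cfg.isomer_delta``.  RI ties go
    to the higher similarity, then the lower bin id.
    """
    if not candidates:
        raise ValueError("resolve_isomers requires at least one candidate")
    cfg = cfg or MatchConfig()
    ri_winner = min(candidates, key=lambda c: (abs(c[0].ri - ri), -c[1], c[0].bin_id))
    sim_winner = max(candidates, key=lambda c: (c[1], -abs(c[0].ri - ri), -c[0].bin_id))
    if sim_winner[1] - ri_winner[1] >= cfg.isomer_delta:
        return sim_winner[0]
    return ri_winner[0]


def annotate_sample(
    peaks: list[DeconvolutedPeak],
    curve: CorrectionCurve,
    bins: list[Bin],
    cfg: MatchConfig | None = None,
    claimed: set[int] | None = None,
    skip_peaks: set[int] | None = None,
    pass_: str = PASS_FIRST,
) -> tuple[list[Annotation], list[tuple[DeconvolutedPeak, float]]]:
    """Sequentially annotate one sample's peaks by decreasing intensity.

    Returns ``(annotations, unannotated)`` where ``unannotated`` holds
    ``(peak, observed_ri)`` pairs that matched no available Bin (these are
    the input to new-Bin generation).  ``claimed``/``skip_peaks`` let the
    post-matching pass respect first-pass assignments (a Bin is annotated
    at most once per sample per pass).
    """
    cfg = cfg or MatchConfig()
    claimed = set() if claimed is None else claimed
    skip_peaks = skip_peaks or set()
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-peaks[i].unique_ion_height, peaks[i].rt, i),
    )
    annotations: list[Annotation] = []
    unannotated: list[tuple[DeconvolutedPeak, float]] = []
    for i in order:
        peak = peaks[i]
        ri = rt_to_ri(curve, peak.rt)
        if i in skip_peaks:
            continue
        available = [b for b in bins if b.bin_id not in claimed]
        cands = candidate_bins(peak, ri, available, cfg)
        min_score = required_similarity(peak.sn, peak.purity, cfg.threshold_schedule)
        scored = [
            (b, s) for b in cands
            if (s := similarity(peak.spectrum, b.spectrum)) >= min_score
        ]
        if not scored:
            unannotated.append((peak, ri))
            continue
        winner = resolve_isomers(scored, ri, cfg)
        win_sim = next(s for b, s in scored if b.bin_id == winner.bin_id)
        claimed.add(winner.bin_id)
        annotations.append(
            Annotation(
                peak=peak,
                bin_id=winner.bin_id,
                sample_id=peak.sample_id,
                similarity=win_sim,
                ri_observed=ri,
                pass_=pass_,
                value=peak.unique_ion_height,
            )
        )
    return annotations, unannotated
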