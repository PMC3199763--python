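"""Post-matching, raw-trace replacement of missing values, and result sheets.

After new Bins are generated, every sample is matched once more against
the full Bin list (post-matching), so Bins created late in a run are
searched everywhere.  Cells still empty are then filled from the raw
chromatograms: the quantifier-ion trace is read around the expected
retention time (the Bin's mean observed RI back-transformed through the
sample's own correction curve), and the background-subtracted maximum in
a ±2 s core window is reported as a replacement value.  Result sheets
list every Bin detected in at least 80% (and, in a companion file, 50%)
of the samples of an experimental class; values are quantifier-mass peak
heights, never areas, and artifact Bins are omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import PASS_FIRST, PASS_POST, Annotation, annotate_sample
from .config import MatchConfig, ReportConfig
from .errors import BinLookupError
from .io_formats import encode_spectrum, read_ion_trace
from .models import DeconvolutedPeak, ExperimentDesign
from .registry import Bin, BinStore
from .ri import CorrectionCurve, ri_to_rt

log = logging.getLogger(__name__)

MATCHED = "MATCHED"
POSTMATCHED = "POSTMATCHED"
REPLACED = "REPLACED"

_PASS_TO_PROVENANCE = {PASS_FIRST: MATCHED, PASS_POST: POSTMATCHED}


@dataclass(frozen=True)
class ReportCell:
    sample_id: str
    bin_id: int
    value: float
    provenance: str  # MATCHED | POSTMATCHED | REPLACED

    def __post_init__(self) -> None:
        if self.provenance == REPLACED and self.value < 0:
            raise ValueError("replacement values are clipped at zero")


def postmatch(
    first_pass: dict[str, list[Annotation]],
    peaks_by_sample: dict[str, list[DeconvolutedPeak]],
    curves: dict[str, CorrectionCurve],
    bins: list[Bin],
    cfg: MatchConfig | None = None,
) -> dict[str, list[Annotation]]:
    """Second annotation pass of all spectra against the full Bin list.

    First-pass assignments are kept (claim-once per sample); spectra that
    failed the stricter Bin-generation gates may still pass the annotation
    thresholds here and gain a POST assignment.
    """
    cfg = cfg or MatchConfig()
    out: dict[str, list[Annotation]] = {}
    for sid, peaks in peaks_by_sample.items():
        prior = first_pass.get(sid, [])
        claimed = {a.bin_id for a in prior}
        done_peaks = {id(a.peak) for a in prior}
        skip = {i for i, p in enumerate(peaks) if id(p) in done_peaks}
        new, _ = annotate_sample(
            peaks, curves[sid], bins, cfg,
            claimed=claimed, skip_peaks=skip, pass_=PASS_POST,
        )
        out[sid] = prior + new
    return out


def replace_missing(
    bin_: Bin,
    mean_ri: float,
    samples_missing: list[str],
    curves: dict[str, CorrectionCurve],
    raw_files: dict[str, str],
    cfg: ReportConfig | None = None,
) -> list[ReportCell]:
    """Fill missing (sample, bin) cells from the raw quantifier-ion trace.

    Per sample the value is ``max`` of the trace in a ±2 s core window
    around the back-transformed target RT, minus the local background
    (a low percentile of the ±5 s flank with the core excluded), clipped
    at zero.  Unreadable raw files yield a zero-valued cell and a warning.
    """
    cfg = cfg or ReportConfig()
    cells: list[ReportCell] = []
    for sid in samples_missing:
        value = 0.0
        try:
            target_rt = ri_to_rt(curves[sid], mean_ri)
            flank = read_ion_trace(
                raw_files[sid], bin_.quantifier_mass,
                target_rt - cfg.flank_half_width, target_rt + cfg.flank_half_width,
            )
            core_vals = [
                v for t, v in flank if abs(t - target_rt) <= cfg.core_half_width
            ]
            bg_vals = [
                v for t, v in flank if abs(t - target_rt) > cfg.core_half_width
            ]
            if core_vals:
                background = (
                    float(np.percentile(bg_vals, cfg.background_percentile))
                    if bg_vals else 0.0
                )
                value = max(0.0, max(core_vals) - background)
        except (OSError, KeyError) as exc:
            log.warning(
                "replacement for bin %d in %s failed (%s); reporting 0",
                bin_.bin_id, sid, exc,
            )
        cells.append(ReportCell(sid, bin_.bin_id, value, REPLACED))
    return cells


def cells_from_annotations(annotations: dict[str, list[Annotation]]) -> list[ReportCell]:
    return [
        ReportCell(a.sample_id, a.bin_id, a.value, _PASS_TO_PROVENANCE[a.pass_])
        for anns in annotations.values() for a in anns
    ]


def build_report(
    cells: list[ReportCell],
    design: ExperimentDesign,
    store: BinStore,
    level: float,
    count_replaced: bool = False,
) -> pd.DataFrame:
    """Assemble one result sheet at a detection level (0.80 or 0.50).

    A Bin is included when, in its best experimental class, the fraction
    of samples with a positive (MATCHED or POSTMATCHED) detection reaches
    ``level``.  Rows carry bin metadata (id, name or "unknown", quantifier
    mass, RI, string-encoded spectrum, external identifier); one column
    per sample holds the quantifier-mass height, with a parallel
    ``provenance:`` column flagging replaced values.
    """
    if not 0 < level <= 1:
        raise ValueError(f"unknown report level {level!r}")
    samples = design.sample_ids
    by_bin: dict[int, dict[str, ReportCell]] = {}
    for c in cells:
        by_bin.setdefault(c.bin_id, {})[c.sample_id] = c
    detected_provs = {MATCHED, POSTMATCHED} | ({REPLACED} if count_replaced else set())
    rows = []
    for bin_id in sorted(by_bin):
        try:
            b = store.get_bin(bin_id)
        except BinLookupError:
            continue
        if b.artifact or b.export_excluded:
            continue
        cell_map = by_bin[bin_id]
        frac = max(
            sum(
                1 for s in members
                if s in cell_map and cell_map[s].provenance in detected_provs
            ) / len(members)
            for members in design.classes.values()
        )
        if frac < level:
            continue
        row: dict = {
            "bin_id": b.bin_id,
            "name": b.name or "unknown",
            "quantifier_mass": b.quantifier_mass,
            "ri": b.ri,
            "spectrum": encode_spectrum(b.spectrum),
            "external_id": ";".join(f"{k}={v}" for k, v in b.external_ids.items()),
        }
        for s in samples:
            cell = cell_map.get(s)
            row[s] = cell.value if cell else 0.0
            row[f"provenance:{s}"] = cell.provenance if cell else "MISSING"
        rows.append(row)
    meta_cols = ["bin_id", "name", "quantifier_mass", "ri", "spectrum", "external_id"]
    cols = meta_cols + samples + [f"provenance:{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
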