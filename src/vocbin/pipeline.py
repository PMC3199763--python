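"""End-to-end orchestration: validate -> RI-correct -> annotate -> generate
Bins -> post-match -> replace -> report.

Each sample is imported, its spectra validated, and its FAME markers
located and fitted into a correction curve.  Samples whose markers fail
are given a borrowed or partial curve (which bars them from seeding new
Bins).  After first-pass annotation, unannotated high-quality spectra
are clustered across samples and admitted as new Bins, all samples are
post-matched against the enlarged Bin list, still-missing cells are
filled from the raw ion traces, and the 80%/50% result sheets are
written together with a JSON provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Annotation, annotate_sample
from .config import EngineConfig
from .errors import CurveFitError, FormatError, UnprocessableSampleError
from .io_formats import read_peak_table
from .models import DeconvolutedPeak, ExperimentDesign
from .registry import Bin, BinStore, generate_bins
from .report import (ReportCell, build_report, cells_from_annotations,
                     postmatch, replace_missing, write_report)
from .ri import (CorrectionCurve, MarkerDef, default_marker_table,
                 fit_correction_curve, locate_fame_markers, resolve_fallback_curve)
from .validation import assess_sample, validate_spectrum

log = logging.getLogger(__name__)


@dataclass
class SampleSummary:
    n_imported: int = 0
    n_skipped_rows: int = 0
    n_discarded: int = 0  # failed spectral validation
    n_marker: int = 0  # consumed as FAME marker hits
    n_annotated: int = 0  # distinct peaks with a FIRST or POST assignment
    n_unannotated: int = 0
    curve_provenance: str = "NONE"


@dataclass
class RunResult:
    store: BinStore
    annotations: dict[str, list[Annotation]]
    cells: list[ReportCell]
    new_bins: list[Bin]
    curves: dict[str, CorrectionCurve]
    summaries: dict[str, SampleSummary]
    skipped_samples: dict[str, str]
    report_paths: dict[float, Path] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        keys = ("n_imported", "n_skipped_rows", "n_discarded", "n_marker",
                "n_annotated", "n_unannotated")
        return {k: sum(getattr(s, k) for s in self.summaries.values()) for k in keys}


def _config_hash(cfg: EngineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_experiment(
    design: ExperimentDesign,
    peak_tables: dict[str, str | Path],
    store: BinStore | str | Path,
    cfg: EngineConfig | None = None,
    out_dir: str | Path | None = None,
    markers: list[MarkerDef] | None = None,
    species: str | None = None,
) -> RunResult:
    """Run the full pipeline over one experiment.

    ``peak_tables`` maps sample_id to its deconvoluted peak-table file.
    Samples that cannot be processed (unreadable table, no obtainable
    correction curve) are skipped with a logged reason; the run continues.
    """
    cfg = cfg or EngineConfig()
    if not isinstance(store, BinStore):
        store = BinStore(store)
    markers = markers or default_marker_table()

    peaks_by_sample: dict[str, list[DeconvolutedPeak]] = {}
    statuses = {}
    summaries: dict[str, SampleSummary] = {}
    skipped_samples: dict[str, str] = {}
    hits_by_sample: dict[str, list] = {}
    curves: dict[str, CorrectionCurve] = {}
    pending_fallback: list[str] = []

    # ---- import, validate, locate markers, fit own curves -----------------
    for sid in design.sample_ids:
        summary = SampleSummary()
        summaries[sid] = summary
        try:
            result = read_peak_table(peak_tables[sid], sample_id=sid)
        except (FormatError, OSError, KeyError) as exc:
            skipped_samples[sid] = f"unreadable peak table: {exc}"
            log.warning("skipping %s: %s", sid, exc)
            continue
        summary.n_imported = len(result.peaks)
        summary.n_skipped_rows = result.n_skipped
        valid = [p for p in result.peaks if validate_spectrum(p, cfg.validation).valid]
        summary.n_discarded = len(result.peaks) - len(valid)
        statuses[sid] = assess_sample(result.peaks, cfg.validation)
        statuses[sid].sample_id = sid
        peaks_by_sample[sid] = valid

        hits = locate_fame_markers(valid, markers, cfg.markers)
        hits_by_sample[sid] = hits
        try:
            curves[sid] = fit_correction_curve(hits, markers, cfg.markers)
        except CurveFitError as exc:
            log.info("%s: own curve failed (%s); deferring to fallback", sid, exc)
            pending_fallback.append(sid)

    # ---- fallback ladder for samples without an own curve -----------------
    own_curves = {
        sid: (design.acquisition_dates.get(sid), curves[sid]) for sid in curves
    }
    for sid in pending_fallback:
        try:
            curve = resolve_fallback_curve(
                sid, design.acquisition_dates.get(sid),
                {s: (d, c) for s, (d, c) in own_curves.items() if d is not None},
                hits_by_sample.get(sid, []), cfg.markers,
            )
        except UnprocessableSampleError as exc:
            skipped_samples[sid] = str(exc)
            log.warning("skipping %s: %s", sid, exc)
            peaks_by_sample.pop(sid, None)
            continue
        curves[sid] = curve
        statuses[sid].ri_fallback_used = True
        statuses[sid].bin_generation_allowed = False

    # ---- first-pass annotation -------------------------------------------
    annotations: dict[str, list[Annotation]] = {}
    unannotated: dict[str, list[tuple[DeconvolutedPeak, float]]] = {}
    analyte_peaks: dict[str, list[DeconvolutedPeak]] = {}
    existing_bins = store.bins()
    for sid, valid in peaks_by_sample.items():
        if sid not in curves:
            continue
        marker_peak_ids = {id(h.peak) for h in hits_by_sample.get(sid, [])}
        analytes = [p for p in valid if id(p) not in marker_peak_ids]
        analyte_peaks[sid] = analytes
        summaries[sid].n_marker = len(valid) - len(analytes)
        summaries[sid].curve_provenance = curves[sid].provenance.kind
        anns, un = annotate_sample(analytes, curves[sid], existing_bins, cfg.matching)
        annotations[sid] = anns
        unannotated[sid] = un

    # ---- new-Bin generation ----------------------------------------------
    new_bins, _rejections = generate_bins(
        unannotated, statuses, design, store, cfg.bins,
        ri_window=cfg.matching.ri_window, species=species,
    )

    # ---- post-matching against the full Bin list --------------------------
    all_bins = store.bins()
    annotations = postmatch(annotations, analyte_peaks, curves, all_bins, cfg.matching)

    for sid in annotations:
        summaries[sid].n_annotated = len(annotations[sid])
        summaries[sid].n_unannotated = (
            len(analyte_peaks[sid]) - len(annotations[sid])
        )

    # ---- replacement of missing values ------------------------------------
    cells = cells_from_annotations(annotations)
    detected_bin_ids = {c.bin_id for c in cells}
    processed = [s for s in design.sample_ids if s in curves]
    for bin_id in sorted(detected_bin_ids):
        b = store.get_bin(bin_id)
        observed = [
            a.ri_observed for anns in annotations.values() for a in anns
            if a.bin_id == bin_id and a.ri_observed is not None
        ]
        mean_ri = float(np.mean(observed)) if observed else b.ri
        have = {c.sample_id for c in cells if c.bin_id == bin_id}
        missing = [s for s in processed if s not in have]
        if missing and design.raw_file_paths:
            cells.extend(replace_missing(
                b, mean_ri, missing, curves, design.raw_file_paths, cfg.report,
            ))

    # ---- reports -----------------------------------------------------------
    result = RunResult(
        store=store, annotations=annotations, cells=cells, new_bins=new_bins,
        curves=curves, summaries=summaries, skipped_samples=skipped_samples,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for level in cfg.report.levels:
            table = build_report(cells, design, store, level,
                                 cfg.report.count_replaced_as_detected)
            path = out / f"result_{int(round(level * 100)):03d}.tsv"
            write_report(table, path)
            result.report_paths[level] = path
        sidecar = {
            "config_hash": _config_hash(cfg),
            "curve_provenance": {
                sid: {
                    "kind": c.provenance.kind,
                    "source": c.provenance.source_sample_id,
                    "day_offset": c.provenance.day_offset,
                } for sid, c in curves.items()
            },
            "skipped_samples": skipped_samples,
            "summary": result.totals,
            "n_new_bins": len(new_bins),
        }
        (out / "run_provenance.json").write_text(json.dumps(sidecar, indent=1))
    return result
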