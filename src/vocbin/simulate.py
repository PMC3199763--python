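"""Ground-truthed synthetic GC-TOF-MS experiments.

Emulates what the real pipeline consumes: per-sample deconvoluted peak
tables containing the C4-C24 FAME marker series (base peak m/z 74) plus
terpene-like analyte peaks at retention times consistent with their true
FAME RI under a per-sample drift, raw ANDI-MS chromatograms with
Gaussian quantifier-ion traces (25 scans/s, including for occurrences
deliberately dropped from the peak tables to exercise replacement), and
a class-structured design file.  Every quantity is recorded as ground
truth so each stage of the pipeline can be checked against what was
generated.

What it does not emulate: real deconvolution behaviour (co-elution
errors, shared fragments between neighbours), detector saturation, and
non-Gaussian peak shapes.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import write_andi_ms, write_design, write_peak_table
from .models import DeconvolutedPeak, ExperimentDesign, Spectrum
from .ri import MarkerDef, default_marker_table

SCAN_RATE_HZ = 25.0
RAW_BASELINE = 100.0
PEAK_SIGMA_S = 1.5  # chromatographic Gaussian width


@dataclass(frozen=True)
class CompoundDef:
    name: str
    spectrum: Spectrum  # relative pattern, base peak 999
    true_ri: float  # FAME RI units
    quantifier: int
    mean_height: float


@dataclass
class FixtureConfig:
    n_classes: int = 3
    samples_per_class: int = 5
    compounds: list[CompoundDef] = field(default_factory=list)  # default library if empty
    drift_model: str = "linear"  # none | linear | polynomial | jitter
    drift_amplitude_s: float = 3.0
    rt_noise_s: float = 0.05
    intensity_noise_rel: float = 0.02
    dropout_rate: float = 0.10
    n_decoys: int = 25
    seed: int = 0
    start_date: _dt.date = _dt.date(2011, 3, 1)
    samples_per_day: int = 6

    def __post_init__(self) -> None:
        if self.drift_model not in ("none", "linear", "polynomial", "jitter"):
            raise ValueError(f"unknown drift model {self.drift_model!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


# fragment pool loosely modelled on terpene EI chemistry; m/z 74/87 are
# reserved for the FAME markers and never appear as analyte base peaks
_FRAGMENT_POOL = (39, 41, 43, 53, 55, 67, 69, 77, 79, 81, 91, 94, 95, 105,
                  107, 108, 119, 120, 121, 133, 134, 136, 147, 150, 161, 189, 204)
_QUANTIFIER_POOL = (93, 91, 105, 119, 121, 136, 81, 79, 95, 107,
                    109, 123, 133, 147, 161, 93, 69, 55, 137, 204)


def builtin_compound_library(n: int = 20) -> list[CompoundDef]:
    """Deterministic set of terpene-like compound definitions.

    True RIs are spaced 32,000 FAME RI units apart inside the marker span;
    two compounds share the quantifier m/z 93 (isomer-style ambiguity at
    the unique-ion level, resolved by RI).
    """
    compounds = []
    for i in range(n):
        rng = np.random.default_rng(7_000 + i)
        quant = _QUANTIFIER_POOL[i % len(_QUANTIFIER_POOL)]
        frags = rng.choice(
            [m for m in _FRAGMENT_POOL if m != quant], size=8, replace=False
        )
        peaks = {int(quant): 999}
        # two strong diagnostic fragments guarantee the strong-peak check
        for j, mz in enumerate(sorted(int(m) for m in frags)):
            peaks[mz] = int(rng.integers(550, 900)) if j < 2 else int(rng.integers(60, 450))
        compounds.append(
            CompoundDef(
                name=f"compound_{i:02d}",
                spectrum=Spectrum(tuple(sorted(peaks.items()))),
                true_ri=300_000.0 + 32_000.0 * i,
                quantifier=quant,
                mean_height=float(rng.integers(8_000, 40_000)),
            )
        )
    return compounds


@dataclass
class GroundTruthOccurrence:
    sample_id: str
    compound: str
    rt: float
    true_ri: float
    apex_height: float
    emitted: bool  # False when dropped from the peak table (raw trace only)


@dataclass
class GroundTruth:
    occurrences: list[GroundTruthOccurrence]
    marker_rts: dict[str, dict[int, float]]  # sample -> carbon -> rt
    shifts: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "occurrences": [vars(o) for o in self.occurrences],
            "marker_rts": self.marker_rts,
            "shifts": self.shifts,
        }, indent=1))


def _nominal_rt_of_ri(true_ri: float, markers: list[MarkerDef]) -> float:
    ris = np.array([m.ri_fame for m in markers])
    rts = np.array([m.nominal_rt for m in markers])
    return float(np.interp(true_ri, ris, rts))


def _shift(cfg: FixtureConfig, rng: np.random.Generator, sample_idx: int, n_samples: int) -> float:
    frac = sample_idx / max(n_samples - 1, 1)
    if cfg.drift_model == "none":
        return 0.0
    if cfg.drift_model == "linear":
        return cfg.drift_amplitude_s * frac
    if cfg.drift_model == "jitter":
        return float(rng.normal(0.0, cfg.drift_amplitude_s / 3.0))
    return cfg.drift_amplitude_s * frac  # polynomial: rt-dependent part added later


def _rt_warp(cfg: FixtureConfig, base_shift: float, rt: float) -> float:
    if cfg.drift_model == "polynomial":
        # drift grows quadratically along the run, scaled by the sequence shift
        u = (rt - 100.0) / 800.0
        return rt + base_shift * u * u
    return rt + base_shift


def generate_experiment(
    cfg: FixtureConfig,
    out_dir: str | Path,
    write_raw: bool = True,
) -> tuple[ExperimentDesign, dict[str, Path], GroundTruth]:
    """Write a complete synthetic experiment; returns design, table paths, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    markers = default_marker_table()
    compounds = cfg.compounds or builtin_compound_library()
    n_samples = cfg.n_classes * cfg.samples_per_class

    classes: dict[str, list[str]] = {}
    sample_ids: list[str] = []
    for c in range(cfg.n_classes):
        label = f"class_{chr(ord('A') + c)}"
        members = [f"sample_{c * cfg.samples_per_class + k:02d}"
                   for k in range(cfg.samples_per_class)]
        classes[label] = members
        sample_ids.extend(members)

    raw_paths: dict[str, str] = {}
    dates: dict[str, _dt.date] = {}
    table_paths: dict[str, Path] = {}
    occurrences: list[GroundTruthOccurrence] = []
    marker_rts: dict[str, dict[int, float]] = {}
    shifts: dict[str, float] = {}

    for idx, sid in enumerate(sample_ids):
        dates[sid] = cfg.start_date + _dt.timedelta(days=idx // cfg.samples_per_day)
        base_shift = _shift(cfg, rng, idx, n_samples)
        shifts[sid] = base_shift
        peaks: list[DeconvolutedPeak] = []

        marker_rts[sid] = {}
        for m in markers:
            rt = _rt_warp(cfg, base_shift, m.nominal_rt) + float(rng.normal(0, cfg.rt_noise_s))
            marker_rts[sid][m.carbon] = rt
            height = float(rng.uniform(30_000, 80_000))
            scale = height / 999.0
            jitter = 1.0 + rng.normal(0, cfg.intensity_noise_rel, len(m.reference_spectrum.peaks))
            pk = tuple(
                (mz, max(1, int(round(inten * scale * j))))
                for (mz, inten), j in zip(m.reference_spectrum.peaks, jitter)
            )
            peaks.append(DeconvolutedPeak(
                sample_id=sid, rt=rt, spectrum=Spectrum(pk), unique_mass=74,
                apex_masses=frozenset({74}), sn=200.0, purity=0.05,
                unique_ion_height=height,
            ))

        raw_events: list[tuple[int, float, float]] = []  # (mz, rt, apex)
        for comp in compounds:
            nominal = _nominal_rt_of_ri(comp.true_ri, markers)
            rt = _rt_warp(cfg, base_shift, nominal) + float(rng.normal(0, cfg.rt_noise_s))
            height = float(comp.mean_height * rng.lognormal(0.0, 0.25))
            emitted = bool(rng.random() >= cfg.dropout_rate)
            occurrences.append(GroundTruthOccurrence(
                sample_id=sid, compound=comp.name, rt=rt,
                true_ri=comp.true_ri, apex_height=height, emitted=emitted,
            ))
            raw_events.append((comp.quantifier, rt, height))
            if not emitted:
                continue
            scale = height / 999.0
            jitter = 1.0 + rng.normal(0, cfg.intensity_noise_rel, len(comp.spectrum.peaks))
            pk = tuple(
                (mz, max(1, int(round(inten * scale * j))))
                for (mz, inten), j in zip(comp.spectrum.peaks, jitter)
            )
            peaks.append(DeconvolutedPeak(
                sample_id=sid, rt=rt, spectrum=Spectrum(pk),
                unique_mass=comp.quantifier, apex_masses=frozenset({comp.quantifier}),
                sn=float(rng.uniform(40, 200)), purity=float(rng.uniform(0.05, 0.6)),
                unique_ion_height=height,
            ))

        for _ in range(cfg.n_decoys):
            frags = rng.choice(_FRAGMENT_POOL, size=6, replace=False)
            base = int(frags[0])
            if rng.random() < 0.2:
                base = 74  # spectrally dissimilar base-peak-74 decoy
            pk_map = {base: int(rng.integers(800, 999))}
            for mz in frags[1:]:
                pk_map.setdefault(int(mz), int(rng.integers(500, 800)))
            spectrum = Spectrum(tuple(sorted(pk_map.items())))
            peaks.append(DeconvolutedPeak(
                sample_id=sid, rt=float(rng.uniform(110, 950)),
                spectrum=spectrum, unique_mass=base,
                apex_masses=frozenset({base}),
                sn=15.0, purity=2.0,  # annotatable but never Bin-eligible
                unique_ion_height=float(rng.uniform(1_000, 3_000)),
            ))

        peaks.sort(key=lambda p: p.rt)
        tpath = out / f"{sid}.txt"
        write_peak_table(peaks, tpath)
        table_paths[sid] = tpath

        if write_raw:
            rpath = out / f"{sid}.cdf"
            _write_raw_file(rpath, raw_events, rng)
            raw_paths[sid] = str(rpath)

    design = ExperimentDesign(classes=classes, raw_file_paths=raw_paths,
                              acquisition_dates=dates)
    # the on-disk design carries raw paths relative to itself (portable,
    # and byte-identical across output directories)
    design_rel = ExperimentDesign(
        classes=classes,
        raw_file_paths={sid: Path(p).name for sid, p in raw_paths.items()},
        acquisition_dates=dates,
    )
    write_design(design_rel, out / "design.txt")
    truth = GroundTruth(occurrences, marker_rts, shifts)
    truth.to_json(out / "ground_truth.json")
    return design, table_paths, truth


def _write_raw_file(
    path: Path,
    events: list[tuple[int, float, float]],
    rng: np.random.Generator,
    rt_start: float = 80.0,
    rt_end: float = 960.0,
) -> None:
    """Gaussian quantifier-ion traces on a noisy baseline, 25 scans/s."""
    times = np.arange(rt_start, rt_end, 1.0 / SCAN_RATE_HZ)
    masses = sorted({mz for mz, _, _ in events})
    n_scans, n_masses = len(times), len(masses)
    grid = np.full((n_scans, n_masses), RAW_BASELINE)
    grid += rng.normal(0, 3.0, size=grid.shape)
    col = {mz: j for j, mz in enumerate(masses)}
    for mz, rt, apex in events:
        grid[:, col[mz]] += apex * np.exp(-0.5 * ((times - rt) / PEAK_SIGMA_S) ** 2)
    grid = np.clip(grid, 0, None)
    mass_row = np.array(masses, dtype=float)
    scan_masses = [mass_row] * n_scans
    scan_intens = [grid[i] for i in range(n_scans)]
    write_andi_ms(path, times, scan_masses, scan_intens)
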