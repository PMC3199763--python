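"""Readers and writers for the formats around the annotation engine.

Peak tables are delimited text exports of vendor deconvolution software
(TAB by default, comma accepted); spectra travel inside them as
space-separated ``mz:intensity`` strings.  Raw chromatograms are ANDI-MS
netCDF scan files, read only for the missing-value replacement step.
Spectral libraries use the NIST MSP dialect, with FAME and Kovats
retention indices carried on ``RI_FAME:`` / ``RI_Kovats:`` header lines.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from scipy.io import netcdf_file

from .errors import FormatError, SpectrumDecodeError
from .models import MZ_MAX, MZ_MIN, DeconvolutedPeak, ExperimentDesign, LibraryEntry, Spectrum

log = logging.getLogger(__name__)

# Default column map for vendor peak-table exports; header vocabularies
# vary across software versions, so every name is configurable.
DEFAULT_COLUMN_MAP = {
    "rt": "R.T. (s)",
    "unique_mass": "UniqueMass",
    "apex_masses": "Apex Masses",
    "sn": "S/N",
    "purity": "Purity",
    "height": "Height",
    "spectrum": "Spectra",
}

MANDATORY_COLUMNS = ("rt", "unique_mass", "sn", "purity", "spectrum")


def decode_spectrum(text: str) -> Spectrum:
    """Decode a string-encoded spectrum.

    Pairs are whitespace-separated ``mz:intensity`` with integer m/z and
    intensity.  Duplicate m/z are merged by summing; centroids outside the
    acquisition range [35, 500] are dropped.
    """
    acc: dict[int, int] = {}
    for token in text.split():
        mz_s, _, int_s = token.partition(":")
        try:
            mz = int(round(float(mz_s)))
            inten = int(round(float(int_s)))
        except ValueError:
            continue
        if inten < 0:
            continue
        if MZ_MIN <= mz <= MZ_MAX:
            acc[mz] = acc.get(mz, 0) + inten
    if not acc:
        raise SpectrumDecodeError(f"no valid mz:intensity pair in {text[:60]!r}")
    return Spectrum(tuple(sorted(acc.items())))


def encode_spectrum(s: Spectrum) -> str:
    """Inverse of :func:`decode_spectrum` on valid spectra."""
    return " ".join(f"{mz}:{inten}" for mz, inten in s.peaks)


@dataclass
class PeakTableResult:
    peaks: list[DeconvolutedPeak]
    n_skipped: int = 0


def _parse_apex_masses(raw: str) -> frozenset[int]:
    if not raw or not raw.strip():
        return frozenset()
    parts = raw.replace("+", " ").replace(",", " ").replace(";", " ").split()
    return frozenset(int(round(float(p))) for p in parts)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_peak_table(
    source: TextIO | str | Path,
    sample_id: str | None = None,
    column_map: dict[str, str] | None = None,
) -> PeakTableResult:
    """Parse a delimited peak-table export into deconvoluted peaks.

    Rows whose spectrum cell cannot be decoded (or whose numeric fields are
    unparseable) are skipped and counted in the returned tally rather than
    aborting the import.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    if isinstance(source, (str, Path)):
        path = Path(source)
        if sample_id is None:
            sample_id = path.stem
        handle: TextIO = path.open("r", newline="")
        close = True
    else:
        handle, close = source, False
        if sample_id is None:
            sample_id = "unknown"
    try:
        first = handle.readline()
        if not first.strip():
            return PeakTableResult([], 0)
        delim = _sniff_delimiter(first)
        reader = csv.DictReader([first] + handle.readlines(), delimiter=delim)
        header = reader.fieldnames or []
        for key in MANDATORY_COLUMNS:
            if cmap[key] not in header:
                raise FormatError(f"peak table missing mandatory column {cmap[key]!r}")
        has_sample_col = "Sample" in header
        peaks: list[DeconvolutedPeak] = []
        skipped = 0
        for row in reader:
            try:
                spectrum = decode_spectrum(row[cmap["spectrum"]])
                height_raw = row.get(cmap["height"], "")
                peaks.append(
                    DeconvolutedPeak(
                        sample_id=row["Sample"] if has_sample_col else sample_id,
                        rt=float(row[cmap["rt"]]),
                        spectrum=spectrum,
                        unique_mass=int(round(float(row[cmap["unique_mass"]]))),
                        apex_masses=_parse_apex_masses(row.get(cmap["apex_masses"], "")),
                        sn=float(row[cmap["sn"]]),
                        purity=float(row[cmap["purity"]]),
                        unique_ion_height=float(height_raw) if height_raw else 0.0,
                    )
                )
            except (SpectrumDecodeError, ValueError, TypeError, KeyError):
                skipped += 1
        if skipped:
            log.warning("peak table %s: skipped %d unparseable rows", sample_id, skipped)
        return PeakTableResult(peaks, skipped)
    finally:
        if close:
            handle.close()


def write_peak_table(peaks: Iterable[DeconvolutedPeak], path: str | Path) -> None:
    """Write peaks back out in the default column vocabulary (TAB)."""
    cols = DEFAULT_COLUMN_MAP
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["Sample", cols["rt"], cols["unique_mass"], cols["apex_masses"],
             cols["sn"], cols["purity"], cols["height"], cols["spectrum"]]
        )
        for p in peaks:
            writer.writerow(
                [p.sample_id, f"{p.rt:.3f}", p.unique_mass,
                 "+".join(str(m) for m in sorted(p.apex_masses)),
                 f"{p.sn:.2f}", f"{p.purity:.4f}", f"{p.unique_ion_height:.0f}",
                 encode_spectrum(p.spectrum)]
            )


# ---------------------------------------------------------------------------
# Raw ion traces (ANDI-MS / netCDF)
# ---------------------------------------------------------------------------

def read_ion_trace(
    raw: str | Path,
    mz: int,
    rt_lo: float,
    rt_hi: float,
    tol: float = 0.5,
) -> list[tuple[float, float]]:
    """Extract one ion trace from an ANDI-MS scan file.

    Returns per-scan ``(rt, intensity)`` for the nearest centroid within
    ``tol`` Th of ``mz`` (0 if no centroid falls in the window), restricted
    to scans with rt in ``[rt_lo, rt_hi]``, sorted by rt.
    """
    if rt_lo >= rt_hi:
        raise ValueError("rt_lo must be < rt_hi")
    try:
        nc = netcdf_file(str(raw), "r", mmap=False)
    except OSError as exc:
        raise IOError(f"cannot open raw file {raw}: {exc}") from exc
    try:
        times = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)
        counts = np.asarray(nc.variables["point_count"][:], dtype=int)
        masses = np.asarray(nc.variables["mass_values"][:], dtype=float)
        intens = np.asarray(nc.variables["intensity_values"][:], dtype=float)
    except KeyError as exc:
        raise IOError(f"{raw} lacks ANDI-MS variable {exc}") from exc
    finally:
        nc.close()
    offsets = np.concatenate(([0], np.cumsum(counts)))
    trace: list[tuple[float, float]] = []
    for i, t in enumerate(times):
        if t < rt_lo or t > rt_hi:
            continue
        lo, hi = offsets[i], offsets[i + 1]
        scan_mz = masses[lo:hi]
        if scan_mz.size == 0:
            trace.append((float(t), 0.0))
            continue
        d = np.abs(scan_mz - mz)
        j = int(np.argmin(d))
        trace.append((float(t), float(intens[lo + j]) if d[j] <= tol else 0.0))
    trace.sort(key=lambda p: p[0])
    return trace


def write_andi_ms(
    path: str | Path,
    scan_times: np.ndarray,
    scan_masses: list[np.ndarray],
    scan_intensities: list[np.ndarray],
) -> None:
    """Write scans in the minimal ANDI-MS netCDF layout."""
    counts = np.array([len(m) for m in scan_masses], dtype=np.int32)
    total = int(counts.sum())
    nc = netcdf_file(str(path), "w")
    try:
        nc.createDimension("scan_number", len(scan_times))
        nc.createDimension("point_number", max(total, 1))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = np.asarray(scan_times, dtype=float)
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = counts
        mv = nc.createVariable("mass_values", "d", ("point_number",))
        iv = nc.createVariable("intensity_values", "d", ("point_number",))
        if total:
            mv[:] = np.concatenate(scan_masses).astype(float)
            iv[:] = np.concatenate(scan_intensities).astype(float)
        else:
            mv[:] = np.zeros(1)
            iv[:] = np.zeros(1)
    finally:
        nc.close()


# ---------------------------------------------------------------------------
# MSP spectral libraries
# ---------------------------------------------------------------------------

def read_msp(source: TextIO | str | Path) -> list[LibraryEntry]:
    """Parse a NIST-dialect MSP library.

    Retention indices are taken from ``RI_FAME:`` / ``RI_Kovats:`` lines
    (also accepted inside a ``Comments:`` field as ``key=value`` tokens).
    Entries lacking both indices, or whose peak count disagrees with
    ``Num Peaks:``, raise :class:`FormatError` naming the entry.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    entries: list[LibraryEntry] = []
    blocks = [b for b in text.replace("\r\n", "\n").split("\n\n") if b.strip()]
    for block in blocks:
        name = ""
        ri_fame: float | None = None
        ri_alkane: float | None = None
        external: dict = {}
        num_peaks: int | None = None
        peak_lines: list[str] = []
        in_peaks = False
        for line in block.splitlines():
            line = line.strip()
            if not line:
                continue
            if in_peaks:
                peak_lines.append(line)
                continue
            key, _, val = line.partition(":")
            key_l = key.strip().lower()
            val = val.strip()
            if key_l == "name":
                name = val
            elif key_l in ("ri_fame", "retentionindex", "retention_index"):
                ri_fame = float(val)
            elif key_l in ("ri_kovats", "ri_alkane", "kovatsri"):
                ri_alkane = float(val)
            elif key_l == "comments":
                for token in val.replace('"', "").split():
                    k, _, v = token.partition("=")
                    if k.lower() == "ri_fame" and v:
                        ri_fame = float(v)
                    elif k.lower() in ("ri_kovats", "ri_alkane") and v:
                        ri_alkane = float(v)
                    elif v:
                        external[k] = v
            elif key_l in ("pubchemid", "pubchem", "inchikey", "inchi"):
                external[key.strip()] = val
            elif key_l == "num peaks":
                num_peaks = int(val)
                in_peaks = True
            elif key_l == "synon":
                pass  # synonyms ignored
        pairs: dict[int, int] = {}
        for pl in peak_lines:
            fields = pl.replace(";", " ").split()
            for mz_s, int_s in zip(fields[0::2], fields[1::2]):
                mz = int(round(float(mz_s)))
                if MZ_MIN <= mz <= MZ_MAX:
                    pairs[mz] = pairs.get(mz, 0) + int(round(float(int_s)))
        if num_peaks is not None and num_peaks != sum(
            1 for pl in peak_lines for _ in pl.replace(";", " ").split()[0::2]
        ):
            raise FormatError(f"MSP entry {name!r}: Num Peaks mismatch")
        if ri_fame is None and ri_alkane is None:
            raise FormatError(f"MSP entry {name!r} carries no retention index")
        if not pairs:
            raise FormatError(f"MSP entry {name!r} has no peaks in range")
        entries.append(
            LibraryEntry(
                name=name,
                spectrum=Spectrum(tuple(sorted(pairs.items()))),
                ri_alkane=ri_alkane,
                ri_fame=ri_fame,
                external_ids=external,
            )
        )
    return entries


def write_msp(entries: Iterable[LibraryEntry], dest: TextIO | str | Path | None = None) -> str:
    """Serialise entries as MSP text, emitting both RI scales when known."""
    out: list[str] = []
    for e in entries:
        lines = [f"Name: {e.name}"]
        if e.ri_fame is not None:
            lines.append(f"RI_FAME: {e.ri_fame:g}")
        if e.ri_alkane is not None:
            lines.append(f"RI_Kovats: {e.ri_alkane:g}")
        for k, v in e.external_ids.items():
            lines.append(f"{k}: {v}")
        lines.append(f"Num Peaks: {len(e.spectrum.peaks)}")
        lines.extend(f"{mz} {inten}" for mz, inten in e.spectrum.peaks)
        out.append("\n".join(lines))
    text = "\n\n".join(out) + "\n"
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Experiment-design files
# ---------------------------------------------------------------------------

def read_design(source: TextIO | str | Path) -> ExperimentDesign:
    """Read a delimited design file (sample_id, class, date, raw_path).

    Relative raw paths are resolved against the design file's directory.
    """
    base: Path | None = None
    if isinstance(source, (str, Path)):
        base = Path(source).parent
        handle: TextIO = Path(source).open("r", newline="")
        close = True
    else:
        handle, close = source, False
    try:
        first = handle.readline()
        delim = _sniff_delimiter(first)
        reader = csv.DictReader([first] + handle.readlines(), delimiter=delim)
        header = reader.fieldnames or []
        for col in ("sample_id", "class"):
            if col not in header:
                raise FormatError(f"design file missing column {col!r}")
        classes: dict[str, list[str]] = {}
        raw_paths: dict[str, str] = {}
        dates: dict[str, _dt.date] = {}
        for row in reader:
            sid = row["sample_id"].strip()
            classes.setdefault(row["class"].strip(), []).append(sid)
            if row.get("raw_path"):
                raw = Path(row["raw_path"].strip())
                if base is not None and not raw.is_absolute():
                    raw = base / raw
                raw_paths[sid] = str(raw)
            if row.get("date"):
                dates[sid] = _dt.date.fromisoformat(row["date"].strip())
        return ExperimentDesign(classes=classes, raw_file_paths=raw_paths, acquisition_dates=dates)
    finally:
        if close:
            handle.close()


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "class", "date", "raw_path"])
        for label, samples in design.classes.items():
            for sid in samples:
                date = design.acquisition_dates.get(sid)
                writer.writerow(
                    [sid, label, date.isoformat() if date else "",
                     design.raw_file_paths.get(sid, "")]
                )
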