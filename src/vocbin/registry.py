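"""The Bin store: persistent tracking of known and unknown compounds.

A *Bin* is one database entry per unique compound — mass spectrum,
retention index, quantifier mass, unique-mass list and a stable integer
identifier — created automatically from high-quality unannotated spectra
and tracked across studies whether or not the compound is ever named.

New Bins are admitted only through stringent gates: spectrum purity below
1.0, signal-to-noise above 25, and detection in at least 80% of the
samples of one experimental class (so that one-off contaminants never
enter the database).  Known column-bleed artifacts (siloxane fragments
m/z 207/221/281/355) stay in the store but are excluded from user
reports.  Library identification converts Adams-style alkane (Kovats)
retention indices onto the FAME RI scale with a second-order polynomial.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import BinGenConfig
from .errors import BinLookupError, CalibrationError
from .io_formats import decode_spectrum, encode_spectrum
from .models import DeconvolutedPeak, LibraryEntry, Spectrum
from .similarity import similarity
from .validation import SampleStatus

ARTIFACT_MZS = frozenset({207, 221, 281, 355})

# rejection reason codes for propose_bin
REJECT_PURITY = "PURITY"
REJECT_SN = "SN"
REJECT_PRESENCE = "PRESENCE"
REJECT_SAMPLE_STATUS = "SAMPLE_STATUS"


@dataclass(frozen=True)
class Bin:
    bin_id: int
    spectrum: Spectrum
    ri: float  # FAME RI units
    quantifier_mass: int
    unique_masses: frozenset[int]
    name: str | None = None
    external_ids: dict = field(default_factory=dict)
    artifact: bool = False
    species_seen: frozenset[str] = frozenset()
    export_excluded: bool = False

    def __post_init__(self) -> None:
        if self.quantifier_mass not in self.spectrum.mz_set:
            raise ValueError("quantifier mass must appear in the spectrum")
        if self.artifact and not self.export_excluded:
            raise ValueError("artifact bins are always export-excluded")


@dataclass(frozen=True)
class Rejection:
    reason: str


class BinStore:
    """Single-file relational store of Bins; ids are never reused."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(
            """CREATE TABLE IF NOT EXISTS bins (
                bin_id INTEGER PRIMARY KEY AUTOINCREMENT,
                spectrum TEXT NOT NULL,
                ri REAL NOT NULL,
                quantifier_mass INTEGER NOT NULL,
                unique_masses TEXT NOT NULL,
                name TEXT,
                external_ids TEXT NOT NULL DEFAULT '{}',
                artifact INTEGER NOT NULL DEFAULT 0,
                species_seen TEXT NOT NULL DEFAULT '[]',
                export_excluded INTEGER NOT NULL DEFAULT 0
            )"""
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    @staticmethod
    def _row_to_bin(row: tuple) -> Bin:
        return Bin(
            bin_id=row[0],
            spectrum=decode_spectrum(row[1]),
            ri=row[2],
            quantifier_mass=row[3],
            unique_masses=frozenset(json.loads(row[4])),
            name=row[5],
            external_ids=json.loads(row[6]),
            artifact=bool(row[7]),
            species_seen=frozenset(json.loads(row[8])),
            export_excluded=bool(row[9]),
        )

    def add_bin(
        self,
        spectrum: Spectrum,
        ri: float,
        quantifier_mass: int,
        unique_masses: frozenset[int] | set[int] | None = None,
        name: str | None = None,
        external_ids: dict | None = None,
        species: str | None = None,
    ) -> Bin:
        masses = sorted(unique_masses or {quantifier_mass})
        cur = self._conn.execute(
            "INSERT INTO bins (spectrum, ri, quantifier_mass, unique_masses, name,"
            " external_ids, species_seen) VALUES (?,?,?,?,?,?,?)",
            (
                encode_spectrum(spectrum), ri, quantifier_mass, json.dumps(masses),
                name, json.dumps(external_ids or {}),
                json.dumps([species] if species else []),
            ),
        )
        self._conn.commit()
        return self.get_bin(cur.lastrowid)

    def get_bin(self, bin_id: int) -> Bin:
        row = self._conn.execute("SELECT * FROM bins WHERE bin_id=?", (bin_id,)).fetchone()
        if row is None:
            raise BinLookupError(f"no bin with id {bin_id}")
        return self._row_to_bin(row)

    def bins(self, include_artifacts: bool = True) -> list[Bin]:
        rows = self._conn.execute("SELECT * FROM bins ORDER BY bin_id").fetchall()
        out = [self._row_to_bin(r) for r in rows]
        if not include_artifacts:
            out = [b for b in out if not b.export_excluded]
        return out

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM bins").fetchone()[0]

    def set_identity(self, bin_id: int, name: str, external_ids: dict | None = None) -> Bin:
        self.get_bin(bin_id)
        self._conn.execute(
            "UPDATE bins SET name=?, external_ids=? WHERE bin_id=?",
            (name, json.dumps(external_ids or {}), bin_id),
        )
        self._conn.commit()
        return self.get_bin(bin_id)

    def mark_artifact(self, bin_id: int, reason: str = "") -> Bin:
        """Flag a bin as an artifact; it disappears from all user reports."""
        b = self.get_bin(bin_id)
        ext = dict(b.external_ids)
        if reason:
            ext["artifact_reason"] = reason
        self._conn.execute(
            "UPDATE bins SET artifact=1, export_excluded=1, external_ids=? WHERE bin_id=?",
            (json.dumps(ext), bin_id),
        )
        self._conn.commit()
        return self.get_bin(bin_id)

    def unmark_artifact(self, bin_id: int) -> Bin:
        self.get_bin(bin_id)
        self._conn.execute(
            "UPDATE bins SET artifact=0, export_excluded=0 WHERE bin_id=?", (bin_id,)
        )
        self._conn.commit()
        return self.get_bin(bin_id)

    def suggested_artifacts(self) -> list[Bin]:
        """Bins whose base peak is a known siloxane bleed fragment.

        Suggestions only — flagging requires an explicit confirm step.
        """
        return [
            b for b in self.bins()
            if not b.artifact and b.spectrum.base_peak_mz in ARTIFACT_MZS
        ]

    def to_library_entries(self, cal: "RiCalibration | None" = None) -> list[LibraryEntry]:
        """Export bins as library entries (FAME RI always, Kovats when known)."""
        entries = []
        for b in self.bins(include_artifacts=False):
            ri_alkane = b.external_ids.get("ri_alkane")
            entries.append(
                LibraryEntry(
                    name=b.name or f"bin_{b.bin_id}",
                    spectrum=b.spectrum,
                    ri_fame=b.ri,
                    ri_alkane=float(ri_alkane) if ri_alkane is not None else None,
                    external_ids={k: v for k, v in b.external_ids.items() if k != "ri_alkane"},
                )
            )
        return entries


# ---------------------------------------------------------------------------
# New-Bin gates
# ---------------------------------------------------------------------------

def propose_bin(
    store: BinStore,
    peak: DeconvolutedPeak,
    ri: float,
    class_presence: float,
    sample_status: SampleStatus,
    cfg: BinGenConfig | None = None,
    species: str | None = None,
) -> Bin | Rejection:
    """Admit an unannotated spectrum as a new Bin, or reject with a reason.

    Gates (all strict, in order of reporting): purity < 1.0, S/N > 25,
    class presence >= 0.80, and the originating sample must be allowed to
    generate Bins (clean chromatogram, own correction curve).
    """
    cfg = cfg or BinGenConfig()
    if not sample_status.bin_generation_allowed or sample_status.ri_fallback_used:
        return Rejection(REJECT_SAMPLE_STATUS)
    if not peak.purity < cfg.max_purity:
        return Rejection(REJECT_PURITY)
    if not peak.sn > cfg.min_sn:
        return Rejection(REJECT_SN)
    if not class_presence >= cfg.min_class_presence:
        return Rejection(REJECT_PRESENCE)
    return store.add_bin(
        spectrum=peak.spectrum,
        ri=ri,
        quantifier_mass=peak.unique_mass,
        unique_masses={peak.unique_mass} | peak.apex_masses,
        species=species,
    )


def cluster_candidates(
    candidates: list[tuple[str, DeconvolutedPeak, float]],
    ri_window: float,
) -> list[list[tuple[str, DeconvolutedPeak, float]]]:
    """Group unannotated (sample_id, peak, ri) triples into compound clusters.

    Spectra are considered the same candidate compound when they share the
    unique mass and their RIs fall within one RI window of the cluster
    seed.  This cross-sample grouping feeds the class-presence gate.
    """
    by_mass: dict[int, list[tuple[str, DeconvolutedPeak, float]]] = {}
    for item in candidates:
        by_mass.setdefault(item[1].unique_mass, []).append(item)
    clusters: list[list[tuple[str, DeconvolutedPeak, float]]] = []
    for mass in sorted(by_mass):
        group = sorted(by_mass[mass], key=lambda t: t[2])
        current: list[tuple[str, DeconvolutedPeak, float]] = []
        for item in group:
            if current and item[2] - current[0][2] > ri_window:
                clusters.append(current)
                current = []
            current.append(item)
        if current:
            clusters.append(current)
    return clusters


def generate_bins(
    unannotated: dict[str, list[tuple[DeconvolutedPeak, float]]],
    statuses: dict[str, SampleStatus],
    design,
    store: BinStore,
    cfg: BinGenConfig | None = None,
    ri_window: float = 2000.0,
    species: str | None = None,
) -> tuple[list[Bin], list[Rejection]]:
    """Cross-sample Bin generation from first-pass leftovers.

    Only spectra that individually pass the purity/SN gates, from samples
    cleared for Bin generation, count toward the class-presence test.
    """
    cfg = cfg or BinGenConfig()
    eligible: list[tuple[str, DeconvolutedPeak, float]] = []
    for sid, items in unannotated.items():
        status = statuses.get(sid)
        if status is None or not status.bin_generation_allowed or status.ri_fallback_used:
            continue
        for peak, ri in items:
            if peak.purity < cfg.max_purity and peak.sn > cfg.min_sn:
                eligible.append((sid, peak, ri))
    new_bins: list[Bin] = []
    rejections: list[Rejection] = []
    for cluster in cluster_candidates(eligible, ri_window):
        samples_in = {sid for sid, _, _ in cluster}
        presence = max(
            len(samples_in & set(members)) / len(members)
            for members in design.classes.values()
        )
        rep_sid, rep_peak, _ = max(cluster, key=lambda t: t[1].unique_ion_height)
        mean_ri = float(np.mean([ri for _, _, ri in cluster]))
        result = propose_bin(
            store, rep_peak, mean_ri, presence, statuses[rep_sid], cfg, species=species
        )
        if isinstance(result, Bin):
            new_bins.append(result)
        else:
            rejections.append(result)
    return new_bins, rejections


# ---------------------------------------------------------------------------
# Alkane <-> FAME retention-index conversion and library identification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiCalibration:
    """Second-order polynomial mapping Kovats units to FAME RI units."""

    coefficients: tuple[float, float, float]  # (a0, a1, a2)
    source_pairs: tuple[tuple[float, float], ...]


def fit_ri_calibration(pairs: list[tuple[float, float]]) -> RiCalibration:
    """Fit the quadratic from (ri_alkane, ri_fame) pairs.

    Exact solve at 3 pairs, least squares above.  The fit must be strictly
    increasing over the span of the source pairs.
    """
    if len(pairs) < 3:
        raise CalibrationError("RI calibration needs at least 3 (alkane, fame) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    a2, a1, a0 = np.polyfit(x, y, 2)
    # derivative a1 + 2*a2*x is linear: checking the span endpoints suffices
    for endpoint in (x.min(), x.max()):
        if a1 + 2 * a2 * endpoint <= 0:
            raise CalibrationError("RI calibration is not strictly increasing over its span")
    return RiCalibration((float(a0), float(a1), float(a2)), tuple((float(a), float(f)) for a, f in pairs))


def alkane_to_fame(cal: RiCalibration, x: float) -> float:
    a0, a1, a2 = cal.coefficients
    return a0 + a1 * x + a2 * x * x


def identify_bins(
    store: BinStore,
    library: list[LibraryEntry],
    cal: RiCalibration | None = None,
    ri_window: float = 6000.0,
    min_score: int = 700,
) -> list[tuple[int, LibraryEntry, int, float]]:
    """Rank library matches for every unidentified, non-artifact Bin.

    Library RIs on the alkane scale are converted to FAME RI via ``cal``.
    Returns ``(bin_id, entry, score, delta_ri)`` tuples sorted per bin by
    decreasing score; the actual assignment of a name is a separate
    confirmation step (:meth:`BinStore.set_identity`).
    """
    results: list[tuple[int, LibraryEntry, int, float]] = []
    for b in store.bins():
        if b.artifact or b.name:
            continue
        per_bin: list[tuple[int, LibraryEntry, int, float]] = []
        for entry in library:
            if entry.ri_fame is not None:
                entry_ri = entry.ri_fame
            elif cal is not None:
                entry_ri = alkane_to_fame(cal, entry.ri_alkane)
            else:
                continue
            d_ri = abs(entry_ri - b.ri)
            if d_ri > ri_window:
                continue
            score = similarity(b.spectrum, entry.spectrum)
            if score >= min_score:
                per_bin.append((b.bin_id, entry, score, d_ri))
        per_bin.sort(key=lambda t: (-t[2], t[3]))
        results.extend(per_bin)
    return results
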