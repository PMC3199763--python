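"""Core domain types for GC-TOF-MS volatile annotation.

The engine operates on unit-mass (integer-centroided) spectra restricted to
the acquisition mass range m/z 35-500.  A deconvoluted peak carries the
metadata the annotation filters consume: retention time, unique ion, apex
ions, signal-to-noise and purity.  Retention times are seconds throughout;
retention indices are FAME RI units (a large-integer scale anchored at
262,214 for FAME C4 and 980,934 for FAME C24).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

MZ_MIN = 35
MZ_MAX = 500


@dataclass(frozen=True)
class Spectrum:
    """An integer-centroided mass spectrum.

    Parameters
    ----------
    peaks:
        ``(mz, intensity)`` pairs, m/z strictly ascending, all within
        [35, 500], at least one pair, intensities non-negative.
    """

    peaks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("spectrum must contain at least one peak")
        prev = None
        for mz, inten in self.peaks:
            if not (MZ_MIN <= mz <= MZ_MAX):
                raise ValueError(f"m/z {mz} outside [{MZ_MIN}, {MZ_MAX}]")
            if inten < 0:
                raise ValueError(f"negative intensity at m/z {mz}")
            if prev is not None and mz <= prev:
                raise ValueError("m/z values must be strictly ascending")
            prev = mz

    @property
    def base_peak_mz(self) -> int:
        """m/z of the maximal intensity (first on ties)."""
        return max(self.peaks, key=lambda p: (p[1], -p[0]))[0]

    @property
    def base_peak_intensity(self) -> int:
        return max(p[1] for p in self.peaks)

    @property
    def mz_set(self) -> frozenset[int]:
        return frozenset(p[0] for p in self.peaks)

    def intensity_at(self, mz: int) -> int:
        for m, i in self.peaks:
            if m == mz:
                return i
        return 0


@dataclass(frozen=True)
class DeconvolutedPeak:
    """One deconvoluted feature from a vendor peak table.

    ``unique_mass`` is the m/z deconvolution chose as specific to this
    peak; ``apex_masses`` are m/z values whose traces apex at the same
    scan.  ``sn`` and ``purity`` feed the adaptive similarity thresholds
    (lower purity means a cleaner peak).
    """

    sample_id: str
    rt: float  # seconds
    spectrum: Spectrum
    unique_mass: int
    apex_masses: frozenset[int]
    sn: float
    purity: float
    unique_ion_height: float

    def __post_init__(self) -> None:
        if self.sn < 0 or self.purity < 0:
            raise ValueError("sn and purity must be non-negative")


@dataclass
class ExperimentDesign:
    """Maps samples to experimental classes, raw files and acquisition dates."""

    classes: dict[str, list[str]]  # class_label -> sample ids
    raw_file_paths: dict[str, str] = field(default_factory=dict)
    acquisition_dates: dict[str, _dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, samples in self.classes.items():
            if not samples:
                raise ValueError(f"class {label!r} is empty")
            for sid in samples:
                if sid in seen:
                    raise ValueError(
                        f"sample {sid!r} assigned to both {seen[sid]!r} and {label!r}"
                    )
                seen[sid] = label

    @property
    def sample_ids(self) -> list[str]:
        return [s for samples in self.classes.values() for s in samples]

    def class_of(self, sample_id: str) -> str:
        for label, samples in self.classes.items():
            if sample_id in samples:
                return label
        raise KeyError(sample_id)


@dataclass(frozen=True)
class LibraryEntry:
    """One spectral-library record with at least one retention index."""

    name: str
    spectrum: Spectrum
    ri_alkane: float | None = None  # Kovats units
    ri_fame: float | None = None  # FAME RI units
    external_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ri_alkane is None and self.ri_fame is None:
            raise ValueError(f"library entry {self.name!r} carries no retention index")
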