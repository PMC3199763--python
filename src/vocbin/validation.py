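"""Spectral validation: the first quality gate.

Each deconvoluted spectrum is checked for the presence and relative
abundance of its unique ion, the presence of all apex masses, and a
minimum number of fragments above an intensity floor.  Chromatograms in
which too many spectra fail (overloaded peaks, deconvolution errors) are
kept for matching against existing database entries but barred from
seeding new ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ValidationConfig
from .models import DeconvolutedPeak

MISSING_UNIQUE_ION = "MISSING_UNIQUE_ION"
LOW_UNIQUE_ABUNDANCE = "LOW_UNIQUE_ABUNDANCE"
MISSING_APEX_MASS = "MISSING_APEX_MASS"
TOO_FEW_STRONG_PEAKS = "TOO_FEW_STRONG_PEAKS"


@dataclass(frozen=True)
class ValidationResult:
    reasons: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return not self.reasons


@dataclass
class SampleStatus:
    sample_id: str
    bin_generation_allowed: bool
    n_valid: int
    n_invalid: int
    # set by the pipeline when the sample runs on a borrowed/partial curve
    ri_fallback_used: bool = False


def validate_spectrum(p: DeconvolutedPeak, cfg: ValidationConfig | None = None) -> ValidationResult:
    """Run all four checks, accumulating failures (no short-circuit)."""
    cfg = cfg or ValidationConfig()
    reasons: list[str] = []
    mzs = p.spectrum.mz_set
    if p.unique_mass not in mzs:
        reasons.append(MISSING_UNIQUE_ION)
    else:
        rel = p.spectrum.intensity_at(p.unique_mass) / p.spectrum.base_peak_intensity
        if rel < cfg.min_unique_rel:
            reasons.append(LOW_UNIQUE_ABUNDANCE)
    if any(m not in mzs for m in p.apex_masses):
        reasons.append(MISSING_APEX_MASS)
    n_strong = sum(1 for _, inten in p.spectrum.peaks if inten >= cfg.apex_intensity_floor)
    if n_strong < cfg.min_strong_peaks:
        reasons.append(TOO_FEW_STRONG_PEAKS)
    return ValidationResult(tuple(reasons))


def assess_sample(
    peaks: list[DeconvolutedPeak], cfg: ValidationConfig | None = None
) -> SampleStatus:
    """Chromatogram-level status deciding whether the sample may seed Bins."""
    cfg = cfg or ValidationConfig()
    if not peaks:
        return SampleStatus("", bin_generation_allowed=False, n_valid=0, n_invalid=0)
    sample_id = peaks[0].sample_id
    n_valid = sum(1 for p in peaks if validate_spectrum(p, cfg).valid)
    n_invalid = len(peaks) - n_valid
    allowed = n_invalid / len(peaks) <= cfg.max_invalid_fraction
    return SampleStatus(sample_id, allowed, n_valid, n_invalid)
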