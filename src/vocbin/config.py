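"""Engine configuration: every numeric threshold in one place.

The YAML layout mirrors the pipeline stages::

    validation: {min_unique_rel, apex_intensity_floor, min_strong_peaks, max_invalid_fraction}
    markers:    {min_similarity, offset_tol, extrapolation_cap, borrow_max_days, nominal_rt}
    matching:   {ri_window, isomer_delta, threshold_schedule}
    bins:       {max_purity, min_sn, min_class_presence}
    report:     {levels, count_replaced_as_detected}

All defaults are overridable per experiment from a single YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ValidationConfig:
    # unique-ion abundance relative to the base peak
    min_unique_rel: float = 0.05
    # counts a fragment must exceed to count as a "strong" peak
    apex_intensity_floor: float = 500.0
    min_strong_peaks: int = 3
    # chromatogram-level ceiling on invalid spectra before bin generation
    # is disabled for the sample
    max_invalid_fraction: float = 0.2


@dataclass
class MarkerConfig:
    """Parameters of the FAME marker search (no RT priors are used)."""

    min_similarity: int = 700  # 0-1000 gate for accepting a marker hit
    base_peak_candidates: tuple[int, ...] = (74, 87)
    # tolerance (s) when walking outward from the anchor using expected
    # inter-marker RT offsets
    offset_tol: float = 15.0
    # RI units beyond the linear extrapolation range before ri_to_rt refuses
    extrapolation_cap: float = 100_000.0
    borrow_max_days: int = 10
    # |head-mid| or |mid-tail| discontinuity (RI units) that triggers a flag
    max_join_discontinuity: float = 500.0


@dataclass
class ThresholdRule:
    """One row of the adaptive similarity schedule; first match wins."""

    min_score: int
    max_purity: float | None = None  # rule applies when purity < max_purity
    min_sn: float | None = None  # ... and sn >= min_sn (when given)

    def matches(self, sn: float, purity: float) -> bool:
        if self.max_purity is not None and not purity < self.max_purity:
            return False
        if self.min_sn is not None and not sn >= self.min_sn:
            return False
        return True


@dataclass
class MatchConfig:
    ri_window: float = 2000.0  # +/- FAME RI units, ~2 s
    isomer_delta: int = 50  # similarity margin for overriding the closest-RI rule
    threshold_schedule: list[ThresholdRule] = field(
        default_factory=lambda: [
            ThresholdRule(min_score=800, max_purity=0.15, min_sn=50.0),
            ThresholdRule(min_score=700, max_purity=1.5),
            ThresholdRule(min_score=600),
        ]
    )

    def __post_init__(self) -> None:
        if self.ri_window <= 0:
            raise ValueError("ri_window must be positive")
        if not self.threshold_schedule or self.threshold_schedule[-1].max_purity is not None:
            raise ValueError("threshold schedule must end with a catch-all rule")


@dataclass
class BinGenConfig:
    """Gates for creating new database entries; stricter than annotation."""

    max_purity: float = 1.0  # accept iff purity < max_purity
    min_sn: float = 25.0  # accept iff sn > min_sn (strict)
    min_class_presence: float = 0.80  # accept iff presence >= this fraction


@dataclass
class ReportConfig:
    levels: tuple[float, ...] = (0.80, 0.50)
    count_replaced_as_detected: bool = False
    # replacement windows (s) around the back-transformed target RT
    core_half_width: float = 2.0
    flank_half_width: float = 5.0
    # background estimator: this percentile of the flank trace (core excluded)
    background_percentile: float = 5.0


@dataclass
class EngineConfig:
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)
    bins: BinGenConfig = field(default_factory=BinGenConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for block_name, block in raw.items():
            target = getattr(cfg, block_name, None)
            if target is None or not isinstance(block, dict):
                continue
            for key, value in block.items():
                if key == "threshold_schedule":
                    target.threshold_schedule = [ThresholdRule(**rule) for rule in value]
                elif hasattr(target, key):
                    setattr(target, key, value)
        return cfg

    def to_dict(self) -> dict:
        return {
            "validation": vars(self.validation).copy(),
            "markers": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in vars(self.markers).items()},
            "matching": {
                "ri_window": self.matching.ri_window,
                "isomer_delta": self.matching.isomer_delta,
                "threshold_schedule": [vars(r).copy() for r in self.matching.threshold_schedule],
            },
            "bins": vars(self.bins).copy(),
            "report": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self.report).items()},
        }
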