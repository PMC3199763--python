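"""Exception hierarchy for the vocbin engine."""


class VocBinError(Exception):
    """Base class for all vocbin errors."""


class FormatError(VocBinError):
    """A structured input file violates its format contract."""


class SpectrumDecodeError(FormatError):
    """A string-encoded spectrum contains no valid mz:intensity pair."""


class CurveFitError(VocBinError):
    """A retention-index correction curve could not be fitted."""


class RiRangeError(VocBinError):
    """A retention index lies beyond the calibrated + extrapolated range."""


class UnprocessableSampleError(VocBinError):
    """No correction curve could be obtained for a sample by any fallback."""


class CalibrationError(VocBinError):
    """An alkane-to-FAME retention index calibration is invalid."""


class BinLookupError(VocBinError):
    """A bin_id does not exist in the store."""
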