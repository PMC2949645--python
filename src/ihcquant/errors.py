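"""Exception hierarchy for the analysis pipeline."""


class IHCQuantError(Exception):
    """Base class for all package errors."""


class ImageFormatError(IHCQuantError):
    """Raised when an image file cannot be read or has an unsupported format."""


class ValidationError(IHCQuantError):
    """Raised when an input violates a documented precondition."""


class DegenerateHistogramError(IHCQuantError):
    """Raised when a histogram has all its mass in a single bin."""


class CalibrationError(IHCQuantError):
    """Raised when a calibration fit is underdetermined or rank-deficient."""


class AggregationError(IHCQuantError):
    """Raised when no defined per-image result is available to average."""


class GenerationError(IHCQuantError):
    """Raised when a synthetic scene cannot be packed as requested."""
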