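"""Exception hierarchy for swimseg."""


class SwimsegError(Exception):
    """Base class for all swimseg errors."""


class InvalidParameterError(SwimsegError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff above Nyquist)."""


class InvalidInputError(SwimsegError, ValueError):
    """An input series violates a precondition (too short, non-finite, ...)."""


class DegenerateInputError(SwimsegError, ValueError):
    """Input carries no usable signal (e.g. rank-0 sample matrix for PCA)."""


class FormatError(SwimsegError, ValueError):
    """A session or annotation file does not match the expected layout."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ValidationError(SwimsegError, ValueError):
    """Ground-truth or report content violates an ordering/consistency invariant."""


class CalibrationError(SwimsegError, ValueError):
    """Functional calibration could not be estimated from the given segments."""


class FrameError(SwimsegError, ValueError):
    """Operation requires anatomical-frame data but got sensor-frame data."""


class DetectionError(SwimsegError, RuntimeError):
    """A detector found no qualifying event in its search window."""

    def __init__(self, message: str, event: str | None = None,
                 location: str | None = None):
        super().__init__(message)
        self.event = event
        self.location = location


class OrderingError(SwimsegError, RuntimeError):
    """Detected phase events violate Push < Glid < StPr < Swim < Turn."""
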