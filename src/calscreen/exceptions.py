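"""Exception types raised across the package."""


class CalscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CalscreenError, ValueError):
    """A parameter is outside its documented range."""


class TraceTooShortError(CalscreenError, ValueError):
    """A trace has too few samples for the requested smoothing window."""


class LayoutError(CalscreenError, ValueError):
    """A plate layout requests more wells than the plate holds."""


class PlateValidationError(CalscreenError, ValueError):
    """Plate map and trace matrix are inconsistent."""


class MissingReferenceError(CalscreenError, ValueError):
    """A plate/vehicle group lacks the reference wells needed for normalization."""
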