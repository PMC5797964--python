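"""Exception hierarchy for the oospindle pipeline.

Every stage raises a subclass of :class:`OospindleError` so batch drivers can
catch one type, record the failing stage, and continue with the next file.
"""


class OospindleError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(OospindleError):
    """Scene geometry is self-contradictory (e.g. coincident spindle poles)."""


class OutOfBoundsError(OospindleError):
    """Scene geometry does not fit inside the requested volume."""


class ParameterError(OospindleError):
    """An operation received an out-of-range or inconsistent parameter."""


class SizeError(OospindleError):
    """A volume is smaller than the filter window that should run on it."""


class DegenerateHistogramError(OospindleError):
    """Histogram has too few populated bins for automatic thresholding."""


class NoOocyteFoundError(OospindleError):
    """Bright-field segmentation produced an empty foreground."""


class NoSpindleFoundError(OospindleError):
    """Microtubule-channel segmentation produced an empty foreground."""


class DegenerateSpindleError(OospindleError):
    """Spindle has zero length; positional metrics are undefined."""


class SlabFractionError(OospindleError):
    """A measurement slab along the spindle axis contains no voxels."""


class NoBleachDetectedError(OospindleError):
    """FRAP trace shows no intensity drop between pre- and post-bleach frames."""


class UndefinedRatioError(OospindleError):
    """Denominator group of an expression ratio has zero mean intensity."""


class FitFailureError(OospindleError):
    """Least-squares recovery fit failed to converge from every start."""

    def __init__(self, message: str, rss_trail=None):
        super().__init__(message)
        self.rss_trail = list(rss_trail) if rss_trail is not None else []


class ConfigurationError(OospindleError):
    """Pipeline configuration is missing keys, has unknown keys, or bad values."""
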