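"""Exception hierarchy shared across the package."""


class FibrinetError(Exception):
    """Base class for all package errors."""


class FormatError(FibrinetError):
    """Input raster has the wrong shape, channel count, or encoding."""


class DegenerateImageError(FibrinetError):
    """Image content cannot support the requested operation (e.g. all zero)."""


class ParameterError(FibrinetError, ValueError):
    """A parameter is out of its documented range."""


class BoundaryError(FibrinetError):
    """A measurement window would extend outside the image."""


class UnknownFiberError(FibrinetError, KeyError):
    """An edit referenced a fiber id that does not exist."""


class WidthMeasurementError(FibrinetError):
    """Diameter could not be measured at this site.

    ``kind`` is ``"unresolved"`` when the perpendicular profile never falls
    to half maximum inside the window, and ``"merged"`` when the profile
    contains more than one peak above half maximum (two unresolved fibers).
    """

    def __init__(self, message: str, kind: str = "unresolved"):
        super().__init__(message)
        self.kind = kind


class FitError(FibrinetError):
    """Distribution fitting failed (degenerate sample or EM non-convergence)."""


class ModeError(FibrinetError):
    """Operation called in the wrong analysis mode (network vs agglomerate)."""


class PackingError(FibrinetError):
    """The requested synthetic object counts do not fit in the field."""


class DependencyError(FibrinetError):
    """A pipeline stage is missing a required upstream result."""
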