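"""Exception hierarchy for icgdyn.

All package-specific failures derive from :class:`IcgdynError` so callers can
catch everything with one clause; subclasses also derive from the closest
builtin (ValueError/RuntimeError) to behave well in generic code.
"""


class IcgdynError(Exception):
    """Base class for all icgdyn errors."""


class InvalidParameterError(IcgdynError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive shape)."""


class FormatError(IcgdynError, ValueError):
    """Input array/file has the wrong layout (channels, dtype, shape)."""


class CalibrationError(IcgdynError, RuntimeError):
    """Kinetic calibration cannot reach the requested milestone targets.

    Carries the best residuals found so the caller can see how far off the
    infeasible combination was.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class TrackingError(IcgdynError, RuntimeError):
    """ROI tracking failed on every frame."""


class ExtractionError(IcgdynError, RuntimeError):
    """Trace extraction produced an empty ROI."""


class UndefinedFeatureError(IcgdynError, RuntimeError):
    """A perfusion milestone is undefined for this trace (flat curve, peak
    too close to the window end, ...). compute_features converts these to
    missing values; direct calls see the exception."""


class DegenerateConfigurationError(IcgdynError, ValueError):
    """Landmark configuration cannot support a warp fit (collinear points)."""


class InsufficientLandmarksError(IcgdynError, RuntimeError):
    """Too few reliable landmark matches between a frame pair."""


class StabilizationError(IcgdynError, RuntimeError):
    """Landmark failures persisted beyond the allowed gap during stabilization."""
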