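"""Exception hierarchy for the wound-analysis pipeline.

Every stage raises a subclass of :class:`WoundKitError` so callers can
distinguish bad inputs from images on which the method legitimately finds
nothing (no skin, no wound, no suture sites).
"""


class WoundKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(WoundKitError, ValueError):
    """An argument violates a documented precondition."""


class ParameterError(WoundKitError, ValueError):
    """A tuning parameter is out of its admissible range."""


class EmptySkinError(WoundKitError):
    """No region passed the skin-color filter; segmentation cannot proceed."""


class EmptyWoundError(WoundKitError):
    """No wound area could be delimited in the image."""


class NoFeaturePointsError(WoundKitError):
    """No suture feature points were found; ROI detection is skipped."""


class UndefinedMetricError(WoundKitError, ZeroDivisionError):
    """A metric denominator is zero (e.g. empty manual mask)."""
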