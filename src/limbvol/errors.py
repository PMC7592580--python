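"""Exception hierarchy for limbvol.

All errors raised by the library derive from :class:`LimbVolError` so callers
can catch the whole family; the concrete subclasses distinguish bad inputs,
degenerate geometry and insufficient data.
"""


class LimbVolError(Exception):
    """Base class for all limbvol errors."""


class InvalidParameterError(LimbVolError, ValueError):
    """A parameter is outside its physically meaningful range."""


class EmptyScanError(LimbVolError, ValueError):
    """A point-cloud capture was requested with zero points."""


class InsufficientStationsError(LimbVolError, ValueError):
    """Fewer than two tape stations; no frustum segment can be formed."""


class StationOrderingError(LimbVolError, ValueError):
    """Tape stations are not strictly increasing along the limb."""


class InvalidSegmentError(LimbVolError, ValueError):
    """A frustum segment has non-positive height or no cross-section."""


class InvalidViewError(LimbVolError, ValueError):
    """Unknown capture-view label."""


class DegeneratePoseError(LimbVolError, ValueError):
    """Landmarks coincide; no arm vector can be derived."""


class AxisEstimationError(LimbVolError, ValueError):
    """Point cloud has no usable principal direction."""


class SliceSkippedError(LimbVolError):
    """A cross-section slab held too few points to estimate a perimeter."""


class InsufficientDataError(LimbVolError, ValueError):
    """Not enough observations for the requested statistic or screen."""


class DegenerateFitError(LimbVolError, ValueError):
    """Regression predictor has zero variance."""
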