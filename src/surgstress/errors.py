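"""Exception hierarchy shared across the pipeline.

Every computational stage raises a subclass of :class:`SurgStressError` so
that table assembly can convert per-metric failures into missing-value flags
without masking genuine programming errors.
"""


class SurgStressError(Exception):
    """Base class for domain errors raised by surgstress."""


class EmptySeriesError(SurgStressError, ValueError):
    """A beat/sample series was empty where data is required."""


class DegenerateVariabilityError(SurgStressError, ValueError):
    """RR variability collapsed to zero; the stress index is undefined."""


class InsufficientDataError(SurgStressError, ValueError):
    """Too few samples inside a window to compute the requested statistic."""


class MissingStreamError(SurgStressError, ValueError):
    """A required sensor stream is absent or does not overlap the window."""


class MissingLandmarkError(SurgStressError, ValueError):
    """A tracked pose landmark has no usable samples in the window."""


class UndefinedRatioError(SurgStressError, ZeroDivisionError):
    """A bimanuality ratio has a zero denominator; the trial is flagged."""


class UndefinedCorrelationError(SurgStressError, ValueError):
    """Correlation undefined (zero variance in one of the variables)."""


class SingleClassError(SurgStressError, ValueError):
    """A classification target contains a single class."""


class DegenerateTargetWarning(UserWarning):
    """Binarized questionnaire target collapsed to a single class."""
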