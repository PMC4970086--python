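"""Exception types shared across the package."""


class ImuQcError(Exception):
    """Base class for all package-specific errors."""


class InvalidQuaternionError(ImuQcError, ValueError):
    """A quaternion with (near) zero norm or wrong shape was supplied."""


class AlignmentError(ImuQcError, ValueError):
    """Two series that must share a time base do not."""


class EmptyInputError(ImuQcError, ValueError):
    """An operation that needs at least one sample received none."""


class IngestionError(ImuQcError, ValueError):
    """Raw stream violates ingestion invariants (e.g. non-monotonic time)."""


class FlatSignalError(ImuQcError, ValueError):
    """Cross-correlation is undefined on a zero-variance signal."""


class AnnotationError(ImuQcError, ValueError):
    """Segment annotations are out of bounds, overlapping or unordered."""


class DegenerateFeatureError(ImuQcError, ValueError):
    """A feature has zero variance on the training partition."""


class NotFittedError(ImuQcError, RuntimeError):
    """A model was used before being fitted."""


class DegenerateTrainingError(ImuQcError, ValueError):
    """The training set does not contain both accept and reject examples."""


class UndefinedMetricError(ImuQcError, ValueError):
    """Sensitivity/specificity requested with an empty reference class."""


class SplitLeakError(ImuQcError, RuntimeError):
    """Training touched data from validation participants."""


class ConfigError(ImuQcError, ValueError):
    """Invalid configuration value."""
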