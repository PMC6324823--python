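"""Exception types raised by analysis operations."""


class CpsynError(ValueError):
    """Base class for analysis-level errors."""


class EstimatorUndefined(CpsynError):
    """The silent-synapse estimator has no value for the given failure rates.

    Raised when F+40 is exactly 0 or 1 (log ratio undefined / division by
    zero) or F-60 is 0. Degenerate rates are a legitimate experimental
    outcome; callers decide whether to exclude the cell or report a flag.
    """


class UnreliableMeasurement(CpsynError):
    """A denominator or reference amplitude lies below the noise floor."""


class ThresholdNotReached(CpsynError):
    """No tested stimulus level satisfied the accuracy criterion."""
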