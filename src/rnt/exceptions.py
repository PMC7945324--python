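"""Exceptions raised by the effect-measure and estimation routines."""


class UndefinedMeasureError(ValueError):
    """A measure is mathematically undefined for the given inputs.

    Raised e.g. for RR/RNT with a zero response rate, or RNT_surv when the
    Kaplan-Meier survival estimate is zero in either arm.
    """


class BoundaryRateError(UndefinedMeasureError):
    """A variance formula is undefined at a boundary rate (0 or 1).

    The message recommends a resampling-based interval instead.
    """


class InestimableError(ValueError):
    """A quantity cannot be estimated from the observed follow-up.

    Raised when an evaluation time lies beyond the largest observed time of a
    Kaplan-Meier curve: the step function is unidentified there and is not
    extrapolated.
    """


class UnstableEstimateError(RuntimeError):
    """Too many resampling replicates were undefined at the requested time."""
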