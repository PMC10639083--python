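"""Exception types shared across the package."""


class MinorIntronError(Exception):
    """Base class for package errors."""


class ParameterError(MinorIntronError, ValueError):
    """A parameter is outside its documented domain."""


class TrainingError(MinorIntronError, ValueError):
    """Scoring-model training cannot proceed (too few or degenerate references)."""


class EstimationError(MinorIntronError, ArithmeticError):
    """An estimator is undefined for the supplied counts (e.g. zero denominator)."""


class InsufficientDataError(MinorIntronError, ValueError):
    """An operation's precondition on minimum data size is not met."""
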