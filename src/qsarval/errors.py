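"""Exception types raised across the validation pipeline."""


class QsarvalError(ValueError):
    """Base class for all package-specific errors."""


class DegenerateInputError(QsarvalError):
    """Input makes a metric undefined (e.g. zero-variance responses, TSS = 0)."""


class SingularDesignError(QsarvalError):
    """Design matrix is rank deficient; an OLS fit is not well posed."""


class UnderdeterminedError(QsarvalError):
    """Fewer cases than parameters (plus intercept); the fit is underdetermined."""


class UndefinedLOOError(QsarvalError):
    """A leverage of 1 makes the leave-one-out residual undefined (saturated fit)."""


class EmptyOverlapError(QsarvalError):
    """Cross-validation curves share no n_fitted range; nothing to overlay."""


class UndefinedCorrelationError(QsarvalError):
    """Rank correlation is undefined because one vector has zero rank variance."""


class SweepAbortedError(QsarvalError):
    """More than the tolerated fraction of fits failed at one sample size."""
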