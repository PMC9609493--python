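"""Exception hierarchy for mrmediate.

All pipeline failures derive from :class:`MRError` so callers can catch one
base class; subclasses distinguish schema, validation, parameter and
numerical failures.
"""


class MRError(Exception):
    """Base class for all mrmediate errors."""


class SchemaError(MRError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(MRError):
    """A row violates a summary-statistic invariant.

    Carries the 1-based data row number (header excluded) when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DuplicateSNPError(ValidationError):
    """The same variant identifier appears more than once in one dataset."""


class ParameterError(MRError):
    """An operation was called with an out-of-range parameter."""


class InsufficientInstrumentsError(MRError):
    """Fewer SNPs than the estimator's minimum."""


class CollinearityError(MRError):
    """The multivariable exposure design matrix is rank deficient."""


class ConvergenceError(MRError):
    """An iterative estimator failed to converge; carries a trace."""

    def __init__(self, message: str, trace=None):
        self.trace = trace or []
        super().__init__(message)
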