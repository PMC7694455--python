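"""Exception hierarchy used across phenokit.

All phenokit-specific failures derive from :class:`PhenokitError` so callers
can catch the package's errors without masking programming errors.
"""


class PhenokitError(Exception):
    """Base class for all phenokit errors."""


class InvalidRecordError(PhenokitError, ValueError):
    """A data record violates a basic invariant (e.g. tmin > tmax)."""


class DomainError(PhenokitError, ValueError):
    """A function was evaluated outside its mathematical domain."""


class ContiguityError(PhenokitError, ValueError):
    """A daily weather series has gaps over the requested window."""


class SourceMixError(PhenokitError, ValueError):
    """Air and soil temperature records were mixed in a single series."""


class InsufficientDataError(PhenokitError, ValueError):
    """Too few observations to fit or test the requested model."""


class UnidentifiableError(PhenokitError, ValueError):
    """The data cannot identify the model parameters (degenerate grouping)."""


class DegenerateSlopeError(PhenokitError, ValueError):
    """A quantile or inverse was requested from a flat (slope zero) curve."""


class ConvergenceError(PhenokitError, RuntimeError):
    """An optimizer failed to converge; carries the optimizer diagnostics."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class ValidationError(PhenokitError, ValueError):
    """Input file or cross-file validation failed; carries the issue list."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = issues or []
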