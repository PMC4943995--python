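"""Exception hierarchy shared across the package."""


class DDCohortError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DDCohortError, ValueError):
    """Raised when user-supplied data violates a precondition (exit code 2 in the CLI)."""


class FitFailureError(DDCohortError, RuntimeError):
    """Raised when a curve fit does not converge or the design is degenerate (exit code 3)."""


class DegenerateCohortError(DDCohortError, RuntimeError):
    """Raised when conditional survival is requested for a cohort whose survivorship is already zero."""
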