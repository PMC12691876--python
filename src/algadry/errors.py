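"""Exception hierarchy shared across the package."""


class AlgadryError(Exception):
    """Base class for all package errors."""


class ValidationError(AlgadryError, ValueError):
    """Input data violates a structural or range invariant."""


class SchemaError(ValidationError):
    """A required column or metadata key is missing from an input file."""


class EmptyInputError(SchemaError):
    """The input file contains no data rows."""


class UnitError(ValidationError):
    """Quantities with incompatible time units were mixed without conversion."""


class InsufficientDataError(ValidationError):
    """Too few usable observations for the requested operation."""


class DegreesOfFreedomError(ValidationError):
    """Statistic undefined: not enough observations relative to parameters."""


class NoDryingError(ValidationError):
    """The series shows no net moisture loss, so the estimate is undefined."""


class NonConvergenceError(AlgadryError, RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
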