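"""Exception hierarchy shared across the package."""


class ThermoclotError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ThermoclotError, ValueError):
    """An input value violates a documented precondition.

    The message names the offending field so CSV-level errors can be
    traced back to a column and row.
    """


class DomainError(ValidationError):
    """A mathematical domain violation (division by zero, log of a
    non-positive quantity, non-positive rate constant)."""


class InsufficientDataError(ThermoclotError, ValueError):
    """Too few usable points to perform a fit or selection."""


class DegenerateProfileError(ThermoclotError, ValueError):
    """A condition profile that cannot be normalized (all activities zero)."""


class SchemaError(ThermoclotError, ValueError):
    """A delimited input file does not match the expected schema.

    Collects row-level offences so a single read reports every bad cell.
    """

    def __init__(self, message: str, offenders: list[str] | None = None):
        self.offenders = offenders or []
        if self.offenders:
            message = message + "\n  " + "\n  ".join(self.offenders)
        super().__init__(message)
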