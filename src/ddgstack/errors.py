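"""Exception hierarchy for ddgstack.

All package-specific failures derive from :class:`DdgStackError` so callers
can catch one base class at pipeline boundaries (e.g. the CLI).
"""


class DdgStackError(Exception):
    """Base class for all ddgstack errors."""


class SchemaError(DdgStackError):
    """A required column / feature is missing or has the wrong shape."""


class TableParseError(DdgStackError):
    """A cell of a delimited-text table failed to parse as a number."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class TableValidationError(DdgStackError):
    """A feature table violates a structural invariant (duplicate ids, NaNs...)."""


class ZeroVarianceError(DdgStackError):
    """A vector required to be non-constant has zero variance."""


class UndefinedCorrelationError(DdgStackError):
    """Pearson correlation requested on constant or too-short input."""


class DegenerateDataError(DdgStackError):
    """Statistical test input is degenerate (e.g. all paired differences zero)."""


class FirewallError(DdgStackError):
    """A leakage-flagged cell has no leakage-safe substitute value."""

    def __init__(self, message: str, offending: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.offending = offending or []


class CalibrationError(DdgStackError):
    """Requested synthetic correlation targets are infeasible."""


class PairingError(DdgStackError):
    """Evaluation results cannot be paired (different repeat counts or seeds)."""


class FitError(DdgStackError):
    """Model fitting failed; carries optimizer diagnostics in the message."""


class ModelKindError(DdgStackError):
    """An operation was requested on an unsupported model kind."""
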