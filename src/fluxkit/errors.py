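"""Exception hierarchy shared across the package."""


class FluxkitError(Exception):
    """Base class for all package errors."""


class IdentifierConflictError(FluxkitError):
    """An identifier (reaction, metabolite, gene) is already in use."""


class LookupError_(FluxkitError):
    """A referenced identifier does not exist in the model."""


class BoundError(FluxkitError):
    """A lower bound exceeds its upper bound."""


class GPRSyntaxError(FluxkitError):
    """Malformed gene-reaction association rule text."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class EquationParseError(FluxkitError):
    """Malformed reaction equation text."""


class FormatError(FluxkitError):
    """Malformed model file (missing column, bad cell, ...)."""


class CapabilityError(FluxkitError):
    """The solver backend lacks a required capability (QP, MILP, ...)."""


class UsageError(FluxkitError):
    """An operation was called with arguments outside its contract."""
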