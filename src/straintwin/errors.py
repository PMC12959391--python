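"""Exception hierarchy shared across the package."""


class StraintwinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StraintwinError):
    """A user-supplied configuration value is invalid."""


class ContractError(StraintwinError, ValueError):
    """An input violates an operation's precondition."""


class NoPathError(StraintwinError):
    """No surface path exists between two points (disconnected mesh)."""


class SynchronizationError(StraintwinError):
    """Squat-peak synchronization could not align the two streams."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(StraintwinError, ValueError):
    """An input is degenerate for the requested operation (e.g. constant series)."""
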