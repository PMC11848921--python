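"""Exception hierarchy shared across the package."""


class PnaseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PnaseqError):
    """A table, config file or registry entry is missing or inconsistent."""


class DomainError(PnaseqError):
    """An argument violates a documented precondition."""


class DesignError(PnaseqError):
    """A reagent-library design is invalid (e.g. not complement-closed)."""


class PeakListParseError(PnaseqError):
    """A peak-list file is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DecodingError(PnaseqError):
    """The decoder cannot establish a ladder origin."""
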