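"""Exception types shared across the package."""


class SegrulesError(Exception):
    """Base class for all segrules errors."""


class ParseError(SegrulesError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(SegrulesError):
    """Input violates a structural invariant (cycle, missing label, ...)."""
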