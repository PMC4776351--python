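"""Exception hierarchy shared across the pipeline stages."""


class WgpscafError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(WgpscafError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class ValidationError(WgpscafError):
    """Input that parsed fine but violates a domain invariant."""
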