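"""Exception types shared across the package."""


class GopredictError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GopredictError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GopredictError, ValueError):
    """An in-memory object violates one of its invariants."""


class MissingIdError(GopredictError, KeyError):
    """A protein or term id was requested but is not present."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""
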