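"""Exception hierarchy shared across the package."""


class GoRingsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GoRingsError):
    """Malformed or unreadable input table."""


class ValidationError(GoRingsError):
    """Structurally valid input that violates a contract or invariant."""
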