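"""Exception hierarchy shared across the package."""


class TscoexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TscoexError):
    """Input data violates a structural or numeric invariant."""


class ParseError(TscoexError):
    """A file could not be interpreted in the declared format."""


class UndefinedGiniError(TscoexError):
    """Gini index requested for an all-zero vector (score undefined)."""
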