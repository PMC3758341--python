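"""Exception types shared across the package."""


class ImcoError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ImcoError, ValueError):
    """A structured input file could not be parsed."""


class ValidationError(ImcoError, ValueError):
    """An input violated a documented contract or invariant."""
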