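"""Exception hierarchy."""


class AbbrexError(Exception):
    """Base class for all package errors."""


class ValidationError(AbbrexError, ValueError):
    """Invalid value, configuration, or domain-object state."""


class ParseError(AbbrexError, ValueError):
    """Malformed input that could not be parsed."""
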