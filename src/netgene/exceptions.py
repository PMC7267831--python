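"""Exception types shared across the package."""


class NetgeneError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NetgeneError, ValueError):
    """A text input file could not be parsed; the message carries the line number."""


class ValidationError(NetgeneError, ValueError):
    """An argument or input violates a documented precondition."""
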