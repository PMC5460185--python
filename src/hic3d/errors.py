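"""Exception hierarchy shared across the package."""


class Hic3dError(Exception):
    """Base class for all package errors."""


class FormatError(Hic3dError):
    """A file does not conform to its documented on-disk format."""


class ValidationError(Hic3dError):
    """Input data violates a documented invariant."""


class ParseError(FormatError):
    """A line of a text file could not be parsed; carries a line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class DegenerateInputError(Hic3dError):
    """Input is structurally valid but carries no usable signal."""
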