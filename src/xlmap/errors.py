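"""Exception hierarchy shared across the package."""


class XLMapError(Exception):
    """Base class for all package errors."""


class FormatError(XLMapError):
    """A file could not be parsed or is missing mandatory columns."""


class RowError(FormatError):
    """A specific row of a table is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataError(XLMapError):
    """Inputs are syntactically valid but semantically inconsistent."""


class DegenerateInputError(XLMapError):
    """The requested statistic is undefined on this input."""
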