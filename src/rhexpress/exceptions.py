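"""Exception hierarchy.

Every error raised by the package derives from :class:`RhexpressError`,
split into configuration/parameter problems (exit code 2 at the CLI) and
data problems (exit code 3).
"""


class RhexpressError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RhexpressError, ValueError):
    """A configuration value or function argument is out of range."""


class DataError(RhexpressError, ValueError):
    """Input data violates a structural contract."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class DesignError(DataError):
    """Sample metadata does not describe a valid experimental design."""


class DegenerateDataError(DataError):
    """The data admits no estimate (e.g. all variances zero, no eligible genes)."""
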