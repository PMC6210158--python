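"""Exception hierarchy.

Exit codes follow the CLI contract: 0 ok, 2 configuration error,
3 input/validation error.
"""


class RefgapError(Exception):
    """Base class for all errors raised by refgap."""

    exit_code = 1


class ConfigError(RefgapError):
    """A configuration value is missing, malformed or out of range."""

    exit_code = 2


class InputError(RefgapError):
    """An input file or in-memory input violates its contract."""

    exit_code = 3


class ParseError(InputError):
    """A line of an input file could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line is not None:
            loc += f"{line}:"
        super().__init__(f"{loc} {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(InputError):
    """Structurally parseable input that violates a semantic invariant."""
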