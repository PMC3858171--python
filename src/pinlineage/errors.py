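"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, everything
else raised by the package -> 3.
"""


class PinLineageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PinLineageError):
    """Invalid configuration (bad parameter values, unknown method names)."""


class InputError(PinLineageError):
    """Structurally valid files but semantically invalid input."""


class ParseError(InputError):
    """Malformed record in an input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class SchemaError(InputError):
    """Cross-file inconsistency (shape mismatch, missing sample metadata)."""


class DegenerateNullError(PinLineageError):
    """Null distribution has zero spread; a z-score is undefined."""
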