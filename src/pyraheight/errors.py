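"""Exception hierarchy shared across the package."""


class PyraheightError(Exception):
    """Base class for all package errors."""


class ValidationError(PyraheightError, ValueError):
    """A data object violates one of its invariants."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line_no: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line_no is not None:
                loc += f":{line_no}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line_no = line_no


class ConfigurationError(PyraheightError, ValueError):
    """A configuration object or argument is invalid."""


class DegenerateInputError(PyraheightError, ValueError):
    """Input is structurally valid but carries no information for the
    requested computation (e.g. monomorphic markers, constant predictor)."""
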