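"""Exception hierarchy for the curation pipeline."""


class AsmCurateError(Exception):
    """Base class for all package errors."""


class ParseError(AsmCurateError):
    """A file could not be parsed in the declared format/dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)


class ValidationError(AsmCurateError):
    """Inputs violate a stated precondition or invariant."""


class NoPeakError(AsmCurateError):
    """A k-mer spectrum has no coverage peak beyond the error valley."""
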