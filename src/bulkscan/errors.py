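"""Exception hierarchy shared across bulkscan modules."""


class BulkscanError(Exception):
    """Base class for all bulkscan errors."""


class MapError(BulkscanError, ValueError):
    """A genomic coordinate falls outside the genetic/physical map."""


class DesignError(BulkscanError, ValueError):
    """A cross design or viability model is inconsistent."""


class CapacityError(BulkscanError, ValueError):
    """An exact enumeration was requested beyond the supported locus count."""


class NoSurvivorsError(BulkscanError, RuntimeError):
    """Rejection sampling produced no surviving seeds within the attempt bound."""


class ConsistencyError(BulkscanError, ValueError):
    """Two inputs that must agree (e.g. table vs panel positions) do not."""


class ParseError(BulkscanError, ValueError):
    """A text input could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
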