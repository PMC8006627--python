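"""Exception hierarchy shared across the package."""


class DeidTextError(Exception):
    """Base class for all package-specific errors."""


class BoundaryMismatchError(DeidTextError):
    """An entity span does not align with token boundaries."""


class ParseError(DeidTextError):
    """A corpus or gazetteer file is malformed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(DeidTextError):
    """Standoff annotation disagrees with the document text."""


class OverlapError(DeidTextError):
    """Entity spans overlap where they must not."""


class AlignmentError(DeidTextError):
    """Gold and predicted token sequences do not line up."""


class SizingError(DeidTextError):
    """A corpus split request cannot be satisfied by the corpus at hand."""


class ConfigurationError(DeidTextError):
    """Invalid configuration key or value."""


class GenerationError(DeidTextError):
    """Synthetic-document generation cannot proceed (e.g. empty gazetteer)."""


class ExhaustionError(DeidTextError):
    """Weighted sampling has no non-excluded entry left to draw."""


class ModelError(DeidTextError):
    """Model construction, training or checkpoint loading failed."""
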