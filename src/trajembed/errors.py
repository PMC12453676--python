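"""Exception hierarchy shared across the pipeline stages."""


class TrajembedError(Exception):
    """Base class for all trajembed errors."""


class FormatError(TrajembedError):
    """An input file could not be read in any supported format."""


class SelectionError(TrajembedError):
    """An atom selection resolved to zero atoms."""


class IntegrityError(TrajembedError):
    """Data violates a structural invariant (shape, symmetry, finiteness)."""


class ArgumentError(TrajembedError, ValueError):
    """An argument is outside its documented domain."""


class ParseError(TrajembedError):
    """A trajembed text artifact is malformed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class TrainingError(TrajembedError):
    """Model training failed or diverged."""


class AlignmentError(TrajembedError):
    """Two per-frame sequences could not be aligned by index."""


class LabelingError(TrajembedError):
    """Region extraction or label assignment failed."""


class SpecError(TrajembedError, ValueError):
    """A synthetic-ensemble or run specification is inconsistent."""
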