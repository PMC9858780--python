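"""Exception hierarchy for divscan.

All errors raised by the library derive from :class:`DivscanError`, so
callers can catch a single type at pipeline boundaries.
"""


class DivscanError(Exception):
    """Base class for all divscan errors."""


class FastaFormatError(DivscanError):
    """Malformed FASTA input (empty record, illegal character, duplicate id)."""


class PatternSyntaxError(DivscanError):
    """Invalid bracket-notation motif pattern."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ParameterError(DivscanError):
    """A parameter value outside its documented range."""


class ContractError(DivscanError):
    """An internal precondition between pipeline stages was violated."""
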