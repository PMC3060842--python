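"""Exception hierarchy for proteokit.

Every domain error derives from :class:`ProteokitError` so callers (and the
CLI) can catch one base class and map it to a nonzero exit status.
"""


class ProteokitError(Exception):
    """Base class for all proteokit domain errors."""


class InvalidSequenceError(ProteokitError):
    """Raised for an empty or otherwise unusable residue sequence."""


class InvalidResidueError(InvalidSequenceError):
    """Raised for a character outside the residue alphabet.

    Carries the offending character and its 1-based position.
    """

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position}"
        )


class InvalidChargeError(ProteokitError):
    """Raised when a charge state below 1 is supplied."""


class InvalidModificationError(ProteokitError):
    """Raised for a modification with a bad target or out-of-range position."""


class InvalidHeaderError(ProteokitError):
    """Raised for an empty or unusable FASTA header line."""


class MalformedFastaError(ProteokitError):
    """Raised for structurally invalid FASTA input; carries a line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"{message} (line {line})")


class MalformedMgfError(ProteokitError):
    """Raised for structurally invalid MGF input; carries a line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"{message} (line {line})")


class UnsupportedFormatError(ProteokitError):
    """Raised for an unsupported image/export format."""


class UnknownFormatError(ProteokitError):
    """Raised when identification-file sniffing matches no known dialect."""


class IdParseError(ProteokitError):
    """Raised for a structurally invalid identification file."""


class UnknownTableError(ProteokitError):
    """Raised when a table to introspect does not exist."""


class UnsupportedTypeError(ProteokitError):
    """Raised for a column type the generator cannot map; names the column."""


class CannotGenerateError(ProteokitError):
    """Raised when a table descriptor cannot back a generated accessor."""


class DuplicateAccessionWarning(UserWarning):
    """Emitted when a FASTA database contains a repeated accession."""


class RankGapWarning(UserWarning):
    """Emitted when an identification file skips rank 1 for a spectrum."""
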