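"""Protein/peptide sequence types and in-silico enzymatic digestion.

All coordinates in this module are 1-based inclusive, the proteomics
convention: the first residue of a protein is position 1 and a peptide
spanning residues 3..7 has start=3, end=7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from . import masses
from .errors import InvalidSequenceError
from .masses import MassTable, STANDARD


@dataclass
class Protein:
    """A protein sequence with its accession and description.

    ``header`` optionally carries the parsed FASTA header the protein was
    read from (see :mod:`proteokit.fasta_io`).
    """

    accession: str
    description: str
    sequence: str
    header: Optional[object] = None

    def validate(self, table: MassTable = STANDARD) -> "Protein":
        """Check the sequence is non-empty, uppercase and in-alphabet."""
        if not self.sequence:
            raise InvalidSequenceError(f"protein {self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise InvalidSequenceError(
                f"protein {self.accession}: sequence must be uppercase"
            )
        table.validate(self.sequence)
        return self


@dataclass(frozen=True)
class Enzyme:
    """A proteolytic cleavage rule.

    Cleavage occurs after any residue in ``cleave_after`` unless the *next*
    residue is in ``restrict_before`` (the classic trypsin-not-before-proline
    rule). ``missed_cleavages_max`` is the default ceiling on missed
    cleavages for :func:`digest`, overridable per call.
    """

    name: str
    cleave_after: frozenset[str]
    restrict_before: frozenset[str] = frozenset()
    missed_cleavages_max: int = 0

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError(f"enzyme {self.name!r}: cleave_after must be non-empty")

    def cleavage_sites(self, sequence: str) -> list[int]:
        """1-based positions i such that the bond after residue i is cut.

        The C-terminal end of the sequence is not listed (it is a natural
        terminus, not a cleavage).
        """
        sites = []
        for i in range(len(sequence) - 1):
            if sequence[i] in self.cleave_after and sequence[i + 1] not in self.restrict_before:
                sites.append(i + 1)
        return sites


#: Built-in enzymes with standard specificities. Users can define more via
#: the Enzyme constructor or the CLI config.
ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("trypsin", frozenset("KR"), frozenset("P"), 2),
        Enzyme("lys-c", frozenset("K"), frozenset(), 2),
        Enzyme("arg-c", frozenset("R"), frozenset(), 2),
        Enzyme("chymotrypsin", frozenset("FWY"), frozenset("P"), 2),
        Enzyme("glu-c", frozenset("E"), frozenset(), 2),
    )
}


@dataclass(frozen=True)
class DigestPeptide:
    """A peptide produced by in-silico digestion.

    ``start``/``end`` are 1-based inclusive positions in the parent protein;
    ``missed_cleavages`` counts internal cleavage sites the peptide spans.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def digest(
    protein: Protein,
    enzyme: Enzyme,
    missed_cleavages: int | None = None,
    table: MassTable = STANDARD,
) -> list[DigestPeptide]:
    """Every peptide producible with 0..missed_cleavages missed cleavages.

    The 0-missed-cleavage peptides, concatenated in order, reconstruct the
    parent sequence.  Output is deterministic: sorted by start position, then
    by length.
    """
    protein.validate(table)
    if missed_cleavages is None:
        missed_cleavages = enzyme.missed_cleavages_max
    seq = protein.sequence
    sites = enzyme.cleavage_sites(seq)
    # fragment boundaries: starts of 0-missed fragments (1-based)
    bounds = [0] + sites + [len(seq)]
    peptides: list[DigestPeptide] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for m in range(missed_cleavages + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(
                DigestPeptide(seq[start - 1 : end], start, end, m)
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def find_peptide(protein: Protein, peptide: str, table: MassTable = STANDARD) -> list[int]:
    """All (possibly overlapping) 1-based start positions of ``peptide``.

    Returns an ascending list; empty when the peptide does not occur.
    Unknown residues in ``peptide`` simply never match, so no error is raised
    for an absent peptide.
    """
    protein.validate(table)
    if not peptide:
        raise InvalidSequenceError("empty peptide")
    hits = []
    start = protein.sequence.find(peptide)
    while start != -1:
        hits.append(start + 1)
        start = protein.sequence.find(peptide, start + 1)
    return hits
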