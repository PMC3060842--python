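"""FASTA reading/writing and heterogeneous-header parsing.

Real protein databases mix several header grammars after the ``>``. This
module auto-detects the dialect of each header by ordered grammar matching —
most specific first (uniprot, then legacy NCBI gi, then IPI), with a generic
first-token/rest fallback — so callers get accession, description and
species fields without knowing where the database came from.

The raw header text is always retained, and writing emits it byte-identically,
so a read/write cycle never perturbs a database.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, TextIO

from .errors import (
    DuplicateAccessionWarning,
    InvalidHeaderError,
    MalformedFastaError,
)
from .sequences import Protein


class Dialect(str, Enum):
    UNIPROT = "uniprot"
    NCBI_GI = "ncbi_gi"
    IPI = "ipi"
    GENERIC = "generic"


@dataclass(frozen=True)
class FastaHeader:
    """A header line decomposed into its constituent parts.

    ``raw`` is the header without the leading ``>`` and round-trips
    byte-identically through :func:`write_fasta`.  ``gi_number`` is only set
    for legacy NCBI gi headers (the deprecated gi is kept secondary; the
    primary accession is the innermost database accession).
    """

    raw: str
    dialect: Dialect
    accession: str
    db_tag: str = ""
    protein_name: str = ""
    description: str = ""
    species: str = ""
    gi_number: str = ""


# >sp|P12345|ALBU_HUMAN Serum albumin OS=Homo sapiens OX=9606 ...
_UNIPROT = re.compile(r"^(sp|tr)\|([A-Za-z0-9-]+)\|(\S+)(?:\s+(.*))?$")
# >gi|12345|ref|NP_000001.1| some protein [Homo sapiens]
_NCBI_GI = re.compile(r"^gi\|(\d+)\|(\w+)\|([^|]+)\|\s*(.*)$")
# >IPI:IPI00022434.4|SWISS-PROT:P02768-1 Tax_Id=9606 Gene_Symbol=ALB Serum albumin
_IPI = re.compile(r"^IPI:(IPI[0-9.]+)(?:\|(\S*))?\s*(.*)$")

# UniProt field keys terminating the free-text protein description
_UNIPROT_FIELDS = re.compile(r"\s+(?:OS|OX|GN|PE|SV)=")
_OS_FIELD = re.compile(r"\bOS=(.*?)(?:\s+(?:OX|GN|PE|SV)=|$)")
_BRACKET_SPECIES = re.compile(r"\[([^\[\]]+)\]\s*$")
_TAXID_FIELD = re.compile(r"\bTax_Id=(\S+)")


def parse_header(line: str) -> FastaHeader:
    """Parse one FASTA header into a :class:`FastaHeader`.

    Accepts the line with or without the leading ``>``.  Dialect detection is
    a pure function of the string; unmatched lines fall back to ``generic``
    (first whitespace-delimited token = accession, remainder = description).
    """
    raw = line[1:] if line.startswith(">") else line
    raw = raw.rstrip("\r\n")
    if not raw.strip():
        raise InvalidHeaderError("empty FASTA header")

    m = _UNIPROT.match(raw)
    if m:
        db_tag, accession, protein_name, rest = m.groups()
        rest = rest or ""
        species_m = _OS_FIELD.search(rest)
        split = _UNIPROT_FIELDS.split(rest, maxsplit=1)
        return FastaHeader(
            raw=raw,
            dialect=Dialect.UNIPROT,
            accession=accession,
            db_tag=db_tag,
            protein_name=protein_name,
            description=split[0].strip(),
            species=species_m.group(1).strip() if species_m else "",
        )

    m = _NCBI_GI.match(raw)
    if m:
        gi, db_tag, accession, rest = m.groups()
        species_m = _BRACKET_SPECIES.search(rest)
        return FastaHeader(
            raw=raw,
            dialect=Dialect.NCBI_GI,
            accession=accession.strip(),
            db_tag=db_tag,
            description=rest.strip(),
            species=species_m.group(1).strip() if species_m else "",
            gi_number=gi,
        )

    m = _IPI.match(raw)
    if m:
        accession, cross_refs, rest = m.groups()
        tax_m = _TAXID_FIELD.search(rest or "")
        return FastaHeader(
            raw=raw,
            dialect=Dialect.IPI,
            accession=accession,
            db_tag="IPI",
            description=(rest or "").strip(),
            species=tax_m.group(1) if tax_m else "",
        )

    parts = raw.split(None, 1)
    return FastaHeader(
        raw=raw,
        dialect=Dialect.GENERIC,
        accession=parts[0],
        description=parts[1].strip() if len(parts) > 1 else "",
    )


def read_fasta(source: TextIO) -> Iterator[Protein]:
    """Iterate the proteins of a FASTA stream, in file order.

    Sequences are concatenated across wrapped lines and uppercased; each
    protein carries its parsed :class:`FastaHeader`.  Sequence data before
    the first header raises :class:`MalformedFastaError` with the line
    number.  Duplicate accessions are permitted but flagged through
    :class:`DuplicateAccessionWarning`.
    """
    header: FastaHeader | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> Protein:
        assert header is not None
        if header.accession in seen:
            warnings.warn(
                f"duplicate accession {header.accession!r}",
                DuplicateAccessionWarning,
                stacklevel=3,
            )
        seen.add(header.accession)
        return Protein(
            accession=header.accession,
            description=header.description,
            sequence="".join(chunks).upper(),
            header=header,
        )

    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header is not None:
                yield flush()
            header = parse_header(stripped)
            chunks = []
        else:
            if header is None:
                raise MalformedFastaError(
                    "sequence data before first '>' header", lineno
                )
            chunks.append(stripped)
    if header is not None:
        yield flush()


def write_fasta(proteins: Iterable[Protein], sink: TextIO, wrap: int = 60) -> None:
    """Write proteins as FASTA.

    Headers are emitted from the raw header text when present (byte-identical
    round trip), otherwise regenerated as ``>accession description``.
    ``wrap`` is the sequence line width; 0 disables wrapping (wrap must be
    0 or >= 10).
    """
    if wrap != 0 and wrap < 10:
        raise ValueError(f"wrap must be 0 or >= 10, got {wrap}")
    for protein in proteins:
        raw = getattr(protein.header, "raw", None)
        if raw:
            sink.write(f">{raw}\n")
        else:
            desc = f" {protein.description}" if protein.description else ""
            sink.write(f">{protein.accession}{desc}\n")
        seq = protein.sequence
        if wrap == 0:
            sink.write(seq + "\n")
        else:
            for i in range(0, len(seq), wrap):
                sink.write(seq[i : i + wrap] + "\n")
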