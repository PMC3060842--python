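"""Engine-agnostic identification model with auto-detecting format adapters.

Search engines report peptide-spectrum matches (PSMs) in mutually
incompatible files.  This module reads three dialects — a Mascot-dat-like
sectioned MIME text, an X!Tandem-like XML and an OMSSA-like CSV — through
one abstraction: every adapter emits the same :class:`SpectrumMatch`
semantics (1-based modification positions, scores copied verbatim with an
orientation flag, ranks starting at 1), so downstream code never branches on
the producing engine.  The dialect is sniffed from the first bytes of the
file; callers never state the format.

The three dialects are deliberately *documented minimal subsets* of the real
formats, defined bit-exactly by :mod:`proteokit.fixtures` (which renders a
ground-truth PSM list into all three).  Full native formats are an extension
point.

Mascot-like dialect: a MIME multipart file whose parts are named sections of
``key=value`` lines — ``parameters`` (search parameters), ``queries``
(``q<i>_title`` URL-encoded, ``q<i>_mz``, ``q<i>_charge``) and ``peptides``
(``q<i>_p<rank>=SEQUENCE,score,mods,accessions`` with mods encoded
``pos:shift:name|...`` and accessions ``;``-separated).

X!Tandem-like dialect: an XML document with a ``bioml`` root, one
``group type="model"`` per PSM candidate set (attributes ``label``, ``z``,
``mz``), containing ``protein label="..."`` elements and ``domain`` elements
(attributes ``seq``, ``expect``, ``rank``) with ``aa`` children for
modifications (``type``, ``at``, ``modified``, ``name``); search parameters
as ``note type="input"`` elements.

OMSSA-like dialect: a CSV with the fixed header row
``Spectrum number, Filename/id, Peptide, E-value, Mass, gi, Accession,
Start, Stop, Defline, Mods, Charge, Theo Mass, P-value, NIST score``; in
this subset Filename/id carries the spectrum title, Mass the precursor m/z,
Accession a ``;``-separated list and Mods the ``pos:shift:name|...``
encoding.  The format has no rank column; ranks are derived from score
orientation (ascending E-value), ties broken by peptide sequence.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from urllib.parse import quote, unquote

from lxml import etree

from .errors import IdParseError, RankGapWarning, UnknownFormatError
from .masses import Modification


class Engine(str, Enum):
    MASCOT_LIKE = "mascot_like"
    XTANDEM_LIKE = "xtandem_like"
    OMSSA_LIKE = "omssa_like"


class ScoreOrientation(str, Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


#: engine → (score_name, orientation); scores are copied verbatim, never
#: normalised across engines.
ENGINE_SCORES: dict[Engine, tuple[str, ScoreOrientation]] = {
    Engine.MASCOT_LIKE: ("ionscore", ScoreOrientation.HIGHER_BETTER),
    Engine.XTANDEM_LIKE: ("expect", ScoreOrientation.LOWER_BETTER),
    Engine.OMSSA_LIKE: ("E-value", ScoreOrientation.LOWER_BETTER),
}

OMSSA_HEADER = (
    "Spectrum number, Filename/id, Peptide, E-value, Mass, gi, Accession, "
    "Start, Stop, Defline, Mods, Charge, Theo Mass, P-value, NIST score"
)


@dataclass(frozen=True)
class SpectrumMatch:
    """One engine-agnostic peptide-spectrum match."""

    spectrum_title: str
    peptide_sequence: str
    modifications: tuple[tuple[int, Modification], ...]
    score: float
    score_name: str
    score_orientation: ScoreOrientation
    charge: int
    precursor_mz: float
    engine: Engine
    protein_accessions: tuple[str, ...]
    rank: int = 1

    def agnostic_fields(self) -> tuple:
        """Every field except the engine-identity triple (engine,
        score_name, score_orientation) — the content that must converge
        across dialect adapters."""
        return (
            self.spectrum_title,
            self.peptide_sequence,
            self.modifications,
            self.score,
            self.charge,
            self.precursor_mz,
            self.protein_accessions,
            self.rank,
        )


@dataclass
class IdFile:
    path: str
    detected_format: Engine
    matches: list[SpectrumMatch]
    search_parameters: dict[str, str] = field(default_factory=dict)


def encode_mods(mods) -> str:
    """``pos:shift:name|...`` wire encoding shared by the dialects."""
    return "|".join(f"{pos}:{mod.mass_shift:.6f}:{mod.name}" for pos, mod in mods)


def decode_mods(text: str) -> tuple[tuple[int, Modification], ...]:
    if not text:
        return ()
    out = []
    for item in text.split("|"):
        pos, shift, name = item.split(":")
        out.append((int(pos), Modification(name=name, mass_shift=float(shift))))
    return tuple(out)


def detect_format(first_bytes: bytes) -> Engine:
    """Sniff the dialect from the first bytes (>= 512 or whole file).

    Stable under a prepended UTF-8 BOM and Windows line endings.  Raises
    :class:`UnknownFormatError` listing the three failed rules.
    """
    text = first_bytes.decode("utf-8", errors="replace")
    text = text.lstrip("\ufeff")
    if "<?xml" in text and "<bioml" in text:
        return Engine.XTANDEM_LIKE
    if "boundary=" in text and "Mascot" in text:
        return Engine.MASCOT_LIKE
    first_line = text.splitlines()[0].strip() if text.strip() else ""
    if first_line == OMSSA_HEADER:
        return Engine.OMSSA_LIKE
    raise UnknownFormatError(
        "unrecognised identification format; failed all sniff rules: "
        "(1) XML declaration with a 'bioml' root token; "
        "(2) MIME multipart boundary with a 'Mascot' token; "
        "(3) first line equal to the documented OMSSA-like CSV header"
    )


def read_identifications(path: str | Path) -> IdFile:
    """Load any supported identification file through auto-detection.

    All adapters emit identical :class:`SpectrumMatch` semantics; matches
    are ordered by (spectrum_title, rank).  A spectrum whose best candidate
    is not rank 1 triggers a :class:`RankGapWarning` but still parses.
    """
    data = Path(path).read_bytes()
    engine = detect_format(data[:4096] if len(data) > 4096 else data)
    text = data.decode("utf-8-sig").replace("\r\n", "\n")
    if engine is Engine.MASCOT_LIKE:
        matches, params = _parse_mascot_like(text)
    elif engine is Engine.XTANDEM_LIKE:
        matches, params = _parse_xtandem_like(data)
    else:
        matches, params = _parse_omssa_like(text)
    matches.sort(key=lambda m: (m.spectrum_title, m.rank))
    _warn_rank_gaps(matches)
    return IdFile(
        path=str(path),
        detected_format=engine,
        matches=matches,
        search_parameters=params,
    )


def _warn_rank_gaps(matches: list[SpectrumMatch]) -> None:
    best: dict[str, int] = {}
    for m in matches:
        best[m.spectrum_title] = min(best.get(m.spectrum_title, m.rank), m.rank)
    for title, rank in best.items():
        if rank != 1:
            warnings.warn(
                f"spectrum {title!r}: best candidate has rank {rank}, not 1",
                RankGapWarning,
                stacklevel=3,
            )


def best_match_per_spectrum(idfile: IdFile) -> list[SpectrumMatch]:
    """The single best match for each spectrum title.

    Rank 1 when ranks are present; otherwise the best score respecting the
    orientation.  Deterministic tie-break by lexicographic peptide sequence.
    Output ordered by spectrum title.
    """
    groups: dict[str, list[SpectrumMatch]] = {}
    for m in idfile.matches:
        groups.setdefault(m.spectrum_title, []).append(m)

    def sort_key(m: SpectrumMatch):
        score = (
            -m.score
            if m.score_orientation is ScoreOrientation.HIGHER_BETTER
            else m.score
        )
        return (m.rank, score, m.peptide_sequence)

    return [min(ms, key=sort_key) for _, ms in sorted(groups.items())]


def rerank(matches: list[SpectrumMatch]) -> list[SpectrumMatch]:
    """Re-assign ranks per spectrum from scores (respecting orientation).

    Stable: a match already ranked r by its engine, whose score order agrees
    with its orientation, keeps rank r.  Ties broken by peptide sequence.
    """
    groups: dict[str, list[SpectrumMatch]] = {}
    for m in matches:
        groups.setdefault(m.spectrum_title, []).append(m)
    out = []
    for title in sorted(groups):
        ms = groups[title]
        ms.sort(
            key=lambda m: (
                -m.score
                if m.score_orientation is ScoreOrientation.HIGHER_BETTER
                else m.score,
                m.peptide_sequence,
            )
        )
        for r, m in enumerate(ms, start=1):
            out.append(
                SpectrumMatch(**{**m.__dict__, "rank": r})
                if m.rank != r
                else m
            )
    return out


# ---------------------------------------------------------------------------
# dialect adapters


_MASCOT_SECTION_NAME = re.compile(r'name="([^"]+)"')
_QPR = re.compile(r"^q(\d+)_p(\d+)$")


def _parse_mascot_like(text: str) -> tuple[list[SpectrumMatch], dict[str, str]]:
    boundary_m = re.search(r"boundary=(\S+)", text)
    if not boundary_m:
        raise IdParseError("mascot-like file: missing MIME boundary declaration")
    boundary = boundary_m.group(1)
    sections: dict[str, dict[str, str]] = {}
    for part in text.split(f"--{boundary}"):
        name_m = _MASCOT_SECTION_NAME.search(part)
        if not name_m:
            continue
        kv: dict[str, str] = {}
        body = part.split("\n\n", 1)
        for line in (body[1] if len(body) > 1 else "").splitlines():
            if "=" in line:
                k, _, v = line.partition("=")
                kv[k.strip()] = v
        sections[name_m.group(1)] = kv

    params = sections.get("parameters", {})
    queries = sections.get("queries", {})
    peptides = sections.get("peptides", {})
    score_name, orientation = ENGINE_SCORES[Engine.MASCOT_LIKE]
    matches = []
    for key, value in peptides.items():
        m = _QPR.match(key)
        if not m:
            continue
        q, rank = m.groups()
        try:
            seq, score, mods, accessions = value.split(",", 3)
            title = unquote(queries[f"q{q}_title"])
            precursor_mz = float(queries[f"q{q}_mz"])
            charge = int(queries[f"q{q}_charge"])
        except (ValueError, KeyError) as exc:
            raise IdParseError(
                f"mascot-like file: bad or incomplete query q{q} ({exc})"
            ) from None
        matches.append(
            SpectrumMatch(
                spectrum_title=title,
                peptide_sequence=seq,
                modifications=decode_mods(mods),
                score=float(score),
                score_name=score_name,
                score_orientation=orientation,
                charge=charge,
                precursor_mz=precursor_mz,
                engine=Engine.MASCOT_LIKE,
                protein_accessions=tuple(a for a in accessions.split(";") if a),
                rank=int(rank),
            )
        )
    return matches, params


def _parse_xtandem_like(data: bytes) -> tuple[list[SpectrumMatch], dict[str, str]]:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise IdParseError(f"xtandem-like file: invalid XML ({exc})") from None
    if root.tag != "bioml":
        raise IdParseError(
            f"xtandem-like file: root element is {root.tag!r}, expected 'bioml'"
        )
    params = {
        note.get("label", ""): (note.text or "").strip()
        for note in root.iter("note")
        if note.get("type") == "input"
    }
    score_name, orientation = ENGINE_SCORES[Engine.XTANDEM_LIKE]
    matches = []
    for group in root.iter("group"):
        if group.get("type") != "model":
            continue
        try:
            title = group.get("label")
            charge = int(group.get("z"))
            precursor_mz = float(group.get("mz"))
        except (TypeError, ValueError):
            raise IdParseError(
                f"xtandem-like file: group id={group.get('id')!r} missing "
                "label/z/mz attributes"
            ) from None
        accessions = tuple(
            p.get("label", "") for p in group.iter("protein")
        )
        for domain in group.iter("domain"):
            mods = tuple(
                (int(aa.get("at")), Modification(
                    name=aa.get("name", aa.get("type", "")),
                    mass_shift=float(aa.get("modified")),
                ))
                for aa in domain.iter("aa")
            )
            matches.append(
                SpectrumMatch(
                    spectrum_title=title,
                    peptide_sequence=domain.get("seq", ""),
                    modifications=mods,
                    score=float(domain.get("expect")),
                    score_name=score_name,
                    score_orientation=orientation,
                    charge=charge,
                    precursor_mz=precursor_mz,
                    engine=Engine.XTANDEM_LIKE,
                    protein_accessions=accessions,
                    rank=int(domain.get("rank", "1")),
                )
            )
    return matches, params


def _parse_omssa_like(text: str) -> tuple[list[SpectrumMatch], dict[str, str]]:
    reader = csv.reader(io.StringIO(text), skipinitialspace=True)
    try:
        header = next(reader)
    except StopIteration:
        raise IdParseError("omssa-like file: empty") from None
    expected = [h.strip() for h in OMSSA_HEADER.split(",")]
    if [h.strip() for h in header] != expected:
        raise IdParseError("omssa-like file: header row does not match subset")
    score_name, orientation = ENGINE_SCORES[Engine.OMSSA_LIKE]
    raw: list[SpectrumMatch] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(expected):
            raise IdParseError(
                f"omssa-like file: line {lineno} has {len(row)} fields, "
                f"expected {len(expected)}"
            )
        (_, title, peptide, evalue, mass, _gi, accession,
         _start, _stop, _defline, mods, charge, _theo, _p, _nist) = row
        raw.append(
            SpectrumMatch(
                spectrum_title=title,
                peptide_sequence=peptide,
                modifications=decode_mods(mods),
                score=float(evalue),
                score_name=score_name,
                score_orientation=orientation,
                charge=int(charge),
                precursor_mz=float(mass),
                engine=Engine.OMSSA_LIKE,
                protein_accessions=tuple(a for a in accession.split(";") if a),
                rank=0,  # no rank column: derived below
            )
        )
    # derive ranks per spectrum from ascending E-value (lower is better)
    groups: dict[str, list[SpectrumMatch]] = {}
    for m in raw:
        groups.setdefault(m.spectrum_title, []).append(m)
    matches = []
    for ms in groups.values():
        ms.sort(key=lambda m: (m.score, m.peptide_sequence))
        for r, m in enumerate(ms, start=1):
            matches.append(SpectrumMatch(**{**m.__dict__, "rank": r}))
    return matches, {}
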