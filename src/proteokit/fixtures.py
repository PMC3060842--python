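"""Deterministic generators for every kind of test input the library reads.

Everything here is a pure function of (seed, spec): the same arguments
always produce byte-identical output, with no global random state.  The
generators exist so the whole library is exercisable without downloading a
single real file — random protein databases in each FASTA header dialect,
random peak lists as MGF, a ground-truth PSM list rendered bit-exactly into
all three identification dialects, spectra with planted theoretical
fragment ions, and random relational schemas for the code generator.

The generators emulate the *shape* of real data (grammars, formats, value
ranges), not its physics: intensities are uniform draws, not fragmentation
propensities, and retention behaviour is not modelled.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace
from io import StringIO
from urllib.parse import quote

from . import fragmentation as _frag
from .errors import ProteokitError
from .fragmentation import NeutralLoss, Series, Tolerance, fragment
from .id_model import (
    ENGINE_SCORES,
    Engine,
    OMSSA_HEADER,
    ScoreOrientation,
    SpectrumMatch,
    encode_mods,
)
from .masses import Modification, mz as _mz, monoisotopic_mass
from .spectra import Spectrum, write_mgf

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_SPECIES = [
    ("Homo sapiens", 9606),
    ("Mus musculus", 10090),
    ("Saccharomyces cerevisiae", 4932),
    ("Escherichia coli", 562),
]

_WORDS = [
    "putative", "kinase", "albumin", "transporter", "ribosomal",
    "membrane", "binding", "protein", "synthase", "receptor",
]

_MODIFICATION_POOL = [
    ("Oxidation", 15.994915, "M"),
    ("Phospho", 79.966331, "S"),
    ("Phospho", 79.966331, "T"),
    ("Deamidated", 0.984016, "N"),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; identical spec + seed → identical bytes."""

    seed: int = 0
    n_proteins: int = 5
    protein_length_range: tuple[int, int] = (30, 120)
    n_spectra: int = 5
    peaks_per_spectrum_range: tuple[int, int] = (10, 60)
    n_psms: int = 3
    schema_count: int = 5


def _rng(spec_or_seed, salt: str) -> random.Random:
    seed = spec_or_seed.seed if isinstance(spec_or_seed, FixtureSpec) else spec_or_seed
    return random.Random(f"{seed}:{salt}")


def random_peptide(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(RESIDUES) for _ in range(length))


# ---------------------------------------------------------------------------
# FASTA


def _description(rng: random.Random) -> str:
    return " ".join(rng.sample(_WORDS, 3)).capitalize()


def make_fasta(spec: FixtureSpec, dialect: str = "uniprot", wrap: int = 60) -> str:
    """A FASTA database whose headers all follow one dialect grammar."""
    rng = _rng(spec, f"fasta:{dialect}")
    out = StringIO()
    for i in range(spec.n_proteins):
        species, taxid = _SPECIES[rng.randrange(len(_SPECIES))]
        desc = _description(rng)
        if dialect == "uniprot":
            acc = f"{rng.choice('OPQ')}{rng.randrange(10000, 99999)}"
            entry = f"{random_peptide(rng, 4)}_{species.split()[0][:5].upper()}"
            header = f"sp|{acc}|{entry} {desc} OS={species} OX={taxid}"
        elif dialect == "ncbi_gi":
            header = (
                f"gi|{rng.randrange(10**6, 10**8)}|ref|NP_{rng.randrange(10**6):06d}.1| "
                f"{desc} [{species}]"
            )
        elif dialect == "ipi":
            header = (
                f"IPI:IPI{rng.randrange(10**8):08d}.{rng.randrange(1, 9)}"
                f"|SWISS-PROT:P{rng.randrange(10000, 99999)} "
                f"Tax_Id={taxid} Gene_Symbol={random_peptide(rng, 3)} {desc}"
            )
        elif dialect == "generic":
            header = f"prot_{i:03d} {desc}"
        else:
            raise ProteokitError(f"unknown FASTA dialect {dialect!r}")
        out.write(f">{header}\n")
        seq = random_peptide(rng, rng.randrange(*spec.protein_length_range))
        for j in range(0, len(seq), wrap):
            out.write(seq[j : j + wrap] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# MGF


def make_mgf(spec: FixtureSpec) -> str:
    """Random centroid peak lists as MGF text."""
    rng = _rng(spec, "mgf")
    spectra = []
    for i in range(spec.n_spectra):
        n = rng.randrange(*spec.peaks_per_spectrum_range)
        mzs = sorted(round(rng.uniform(100.0, 1800.0), 4) for _ in range(n))
        intensities = [round(rng.uniform(1.0, 5000.0), 2) for _ in range(n)]
        charge = rng.choice([1, 2, 2, 3])
        spectra.append(
            Spectrum(
                mz=mzs,
                intensity=intensities,
                precursor_mz=round(rng.uniform(300.0, 1200.0), 4),
                precursor_charge=charge,
                title=f"fixture scan {i + 1}",
            )
        )
    sink = StringIO()
    write_mgf(spectra, sink)
    return sink.getvalue()


def make_spectrum_for(
    peptide: str,
    series_set=(Series.B, Series.Y),
    noise_peaks: int = 0,
    seed: int = 0,
    max_charge: int = 1,
    jitter: float = 0.002,
) -> Spectrum:
    """A spectrum containing every theoretical ion of ``peptide`` as a
    planted peak (m/z jittered by at most ``jitter`` Th, well inside a 0.01
    Da tolerance) plus ``noise_peaks`` uniform noise peaks kept at least
    0.05 Th away from every planted position, so annotation at tight
    tolerance always recovers the planted ions."""
    rng = random.Random(f"{seed}:spectrum:{peptide}")
    ions = fragment(peptide, series_set=series_set, max_charge=max_charge)
    planted = [ion.mz + rng.uniform(-jitter, jitter) for ion in ions]
    mzs = list(planted)
    intensities = [round(rng.uniform(200.0, 1000.0), 2) for _ in planted]
    lo, hi = 100.0, max(planted, default=500.0) * 1.2
    attempts = 0
    while len(mzs) < len(planted) + noise_peaks and attempts < 100 * (noise_peaks + 1):
        attempts += 1
        candidate = rng.uniform(lo, hi)
        if all(abs(candidate - p) > 0.05 for p in planted):
            mzs.append(candidate)
            intensities.append(round(rng.uniform(1.0, 150.0), 2))
    precursor = _mz(monoisotopic_mass(peptide), 2)
    return Spectrum(
        mz=mzs,
        intensity=intensities,
        precursor_mz=precursor,
        precursor_charge=2,
        title=f"synthetic spectrum of {peptide}",
    )


# ---------------------------------------------------------------------------
# identifications


@dataclass(frozen=True)
class GroundTruthPsm:
    """Engine-agnostic ground truth; what every adapter must reproduce."""

    spectrum_title: str
    peptide_sequence: str
    modifications: tuple[tuple[int, Modification], ...]
    score: float
    charge: int
    precursor_mz: float
    protein_accessions: tuple[str, ...]
    rank: int = 1

    def agnostic_fields(self) -> tuple:
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


def _ground_truth(spec: FixtureSpec) -> list[GroundTruthPsm]:
    rng = _rng(spec, "psms")
    psms = []
    for i in range(spec.n_psms):
        peptide = random_peptide(rng, rng.randrange(7, 18))
        mods = []
        for pos, ch in enumerate(peptide, start=1):
            for name, shift, target in _MODIFICATION_POOL:
                if ch == target and rng.random() < 0.15:
                    mods.append((pos, Modification(name=name, mass_shift=shift)))
                    break
        charge = rng.choice([2, 2, 3])
        mass = monoisotopic_mass(peptide) + sum(m.mass_shift for _, m in mods)
        psms.append(
            GroundTruthPsm(
                spectrum_title=f"scan {i + 1:04d}, fixture run",
                peptide_sequence=peptide,
                modifications=tuple(mods),
                score=round(rng.uniform(5.0, 95.0), 4),
                charge=charge,
                precursor_mz=round(_mz(mass, charge), 4),
                protein_accessions=tuple(
                    sorted(f"ACC{rng.randrange(1000):04d}" for _ in range(rng.choice([1, 1, 2])))
                ),
                rank=1,
            )
        )
    return psms


def write_mascot_like(psms, parameters=None) -> str:
    """Render PSMs in the Mascot-like sectioned MIME dialect."""
    boundary = "gc0p4Jq0M2Yt08jU534c0p"
    parameters = parameters or {"SEARCH": "MIS", "DB": "fixture", "TOL": "0.01"}
    titles: dict[str, int] = {}
    for p in psms:
        titles.setdefault(p.spectrum_title, len(titles) + 1)
    out = StringIO()
    out.write("MIME-Version: 1.0 (Generated by a Mascot-like fixture writer)\n")
    out.write(f"Content-Type: multipart/mixed; boundary={boundary}\n\n")

    def section(name: str, lines: list[str]) -> None:
        out.write(f"--{boundary}\n")
        out.write(f'Content-Type: application/x-Mascot; name="{name}"\n\n')
        for line in lines:
            out.write(line + "\n")

    section("parameters", [f"{k}={v}" for k, v in parameters.items()])
    query_lines = []
    by_title = {}
    for p in psms:
        by_title.setdefault(p.spectrum_title, p)
    for title, q in titles.items():
        p = by_title[title]
        query_lines += [
            f"q{q}_title={quote(title)}",
            f"q{q}_mz={p.precursor_mz:.4f}",
            f"q{q}_charge={p.charge}",
        ]
    section("queries", query_lines)
    peptide_lines = [
        f"q{titles[p.spectrum_title]}_p{p.rank}="
        f"{p.peptide_sequence},{p.score},{encode_mods(p.modifications)},"
        f"{';'.join(p.protein_accessions)}"
        for p in psms
    ]
    section("peptides", peptide_lines)
    out.write(f"--{boundary}--\n")
    return out.getvalue()


def write_xtandem_like(psms, parameters=None) -> str:
    """Render PSMs in the X!Tandem-like XML dialect."""
    from lxml import etree

    parameters = parameters or {"spectrum, path": "fixture.mgf"}
    root = etree.Element("bioml", label="fixture model set")
    groups: dict[str, etree._Element] = {}
    for i, p in enumerate(psms):
        g = groups.get(p.spectrum_title)
        if g is None:
            g = etree.SubElement(
                root,
                "group",
                type="model",
                id=str(len(groups) + 1),
                label=p.spectrum_title,
                z=str(p.charge),
                mz=f"{p.precursor_mz:.4f}",
            )
            groups[p.spectrum_title] = g
            for acc in p.protein_accessions:
                etree.SubElement(g, "protein", label=acc)
        domain = etree.SubElement(
            g,
            "domain",
            seq=p.peptide_sequence,
            expect=repr(p.score),
            rank=str(p.rank),
        )
        for pos, mod in p.modifications:
            etree.SubElement(
                domain,
                "aa",
                type=p.peptide_sequence[pos - 1],
                at=str(pos),
                modified=f"{mod.mass_shift:.6f}",
                name=mod.name,
            )
    for label, value in parameters.items():
        note = etree.SubElement(root, "note", type="input", label=label)
        note.text = value
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()


def write_omssa_like(psms) -> str:
    """Render PSMs in the OMSSA-like CSV dialect."""
    import csv

    out = StringIO()
    out.write(OMSSA_HEADER + "\n")
    writer = csv.writer(out, lineterminator="\n")
    for i, p in enumerate(psms, start=1):
        writer.writerow(
            [
                i,
                p.spectrum_title,
                p.peptide_sequence,
                repr(p.score),
                f"{p.precursor_mz:.4f}",
                0,
                ";".join(p.protein_accessions),
                1,
                len(p.peptide_sequence),
                "fixture",
                encode_mods(p.modifications),
                p.charge,
                f"{p.precursor_mz:.4f}",
                repr(p.score),
                0,
            ]
        )
    return out.getvalue()


def make_identifications(spec: FixtureSpec):
    """Ground truth plus its rendering in all three dialects.

    Returns ``(psms, files)`` with ``files`` an Engine → file-text dict.
    One candidate per spectrum: scores are written verbatim into every
    dialect, so identical ranks under opposing score orientations require a
    single candidate per spectrum (multi-rank fixtures are per-engine, see
    :func:`make_ranked_identifications`).
    """
    psms = _ground_truth(spec)
    files = {
        Engine.MASCOT_LIKE: write_mascot_like(psms),
        Engine.XTANDEM_LIKE: write_xtandem_like(psms),
        Engine.OMSSA_LIKE: write_omssa_like(psms),
    }
    return psms, files


def make_ranked_identifications(
    spec: FixtureSpec, engine: Engine, ranks_per_spectrum: int = 2
):
    """A single-engine file with several ranked candidates per spectrum.

    Scores are generated consistently with the engine's orientation (rank 1
    is always the best score), which is impossible across engines with
    verbatim scores; hence one file per call.
    """
    rng = _rng(spec, f"ranked:{engine.value}")
    _, orientation = ENGINE_SCORES[engine]
    base = _ground_truth(spec)
    psms = []
    for p in base:
        scores = sorted(
            {round(rng.uniform(1.0, 99.0), 4) for _ in range(ranks_per_spectrum + 2)},
            reverse=orientation is ScoreOrientation.HIGHER_BETTER,
        )[:ranks_per_spectrum]
        for r, s in enumerate(scores, start=1):
            candidate = p.peptide_sequence if r == 1 else random_peptide(
                rng, len(p.peptide_sequence)
            )
            psms.append(
                replace(
                    p,
                    peptide_sequence=candidate,
                    modifications=p.modifications if r == 1 else (),
                    score=s,
                    rank=r,
                )
            )
    writer = {
        Engine.MASCOT_LIKE: write_mascot_like,
        Engine.XTANDEM_LIKE: write_xtandem_like,
        Engine.OMSSA_LIKE: write_omssa_like,
    }[engine]
    return psms, writer(psms)


# ---------------------------------------------------------------------------
# relational schemas


@dataclass(frozen=True)
class SchemaFixture:
    """One random table: its DDL, seed values and an update mutation."""

    table_name: str
    create_sql: str
    values: dict
    mutate: dict
    has_audit: bool


_SQL_TYPES = {
    "integer": "INTEGER",
    "real": "REAL",
    "text": "TEXT",
    "blob": "BLOB",
    "timestamp": "TIMESTAMP",
}


def _random_value(rng: random.Random, ctype: str):
    if ctype == "integer":
        return rng.randrange(-(10**6), 10**6)
    if ctype == "real":
        return round(rng.uniform(-1000.0, 1000.0), 6)
    if ctype == "text":
        return "".join(rng.choice(string.ascii_letters) for _ in range(rng.randrange(3, 20)))
    if ctype == "blob":
        return rng.randbytes(rng.randrange(8, 1024))
    return f"2011-03-{rng.randrange(1, 28):02d} {rng.randrange(24):02d}:00:00+00:00"


def make_schema(spec: FixtureSpec) -> list[SchemaFixture]:
    """Random table fixtures spanning all five column types.

    Every table gets an auto-generated integer key and at least one payload
    column; roughly half also get the creationdate/modificationdate audit
    pair.
    """
    rng = _rng(spec, "schema")
    fixtures = []
    for i in range(spec.schema_count):
        name = f"fixture_table_{i}"
        n_payload = rng.randrange(1, 7)
        cols = [("id", "integer")]
        for j in range(n_payload):
            cols.append((f"col_{j}", rng.choice(list(_SQL_TYPES))))
        has_audit = rng.random() < 0.5
        if has_audit:
            cols += [("creationdate", "timestamp"), ("modificationdate", "timestamp")]
        defs = ['"id" INTEGER PRIMARY KEY']
        defs += [f'"{c}" {_SQL_TYPES[t]}' for c, t in cols[1:]]
        create = f'CREATE TABLE "{name}" ({", ".join(defs)})'
        values = {c: _random_value(rng, t) for c, t in cols[1 : 1 + n_payload]}
        mutate_col, mutate_type = cols[1]
        new_value = _random_value(rng, mutate_type)
        while new_value == values[mutate_col]:
            new_value = _random_value(rng, mutate_type)
        mutate = {mutate_col: new_value}
        fixtures.append(
            SchemaFixture(
                table_name=name,
                create_sql=create,
                values=values,
                mutate=mutate,
                has_audit=has_audit,
            )
        )
    return fixtures
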