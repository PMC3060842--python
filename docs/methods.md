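# Methods

This note records the models, conventions and numerical choices behind
proteokit, and what its generated test data does and does not emulate.

## Mass model

All constants live in one plain-text resource
(`src/proteokit/data/residue_masses.tsv`): monoisotopic residue masses to
six decimals computed from the IUPAC standard atomic masses, average masses
to four, plus the proton (1.007276 Da) and water (18.010565 Da
monoisotopic).  A residue mass is the amino-acid mass minus one water; the
neutral peptide mass is the residue sum plus one water, so mass is additive
under concatenation up to one water — the identity the acceptance suite
checks to 10⁻⁹ Da.

The default alphabet is the 20 standard residues.  Ambiguity codes (B, Z,
X) and nonstandard residues are rejected with an error naming the character
and its 1-based position: failing loudly beats silently averaging.  A
permissive table adds selenocysteine (U) and pyrrolysine (O) at their own
masses; note their monoisotopic/average difference exceeds the 0.2 Da band
that holds for the standard twenty (selenium's isotope pattern), which is
why they are an opt-in extension rather than default rows.

Modification positions follow 0 = N-terminus, 1..n = residues, n+1 =
C-terminus, making terminal chemistry unambiguous without a separate API.

## Digestion

Cleavage sites are bonds after a residue in the enzyme's `cleave_after` set
whose following residue is not in `restrict_before` (trypsin: K/R not
before P).  Peptides with m missed cleavages are joins of m+1 adjacent
zero-missed fragments.  Coordinates are 1-based inclusive throughout, the
field's convention.  The built-in table (trypsin, Lys-C, Arg-C,
chymotrypsin high-specificity, Glu-C) uses the standard textbook
specificities; enzymes are plain values, so nonstandard rules are one
constructor call.  Semi- and non-specific digestion are out of scope.  The
implementation is checked against an O(n²) all-substring enumerator that
re-derives validity from the cleavage rule alone.

## Fragmentation and annotation

Series offsets from b and y: a = b − CO, c = b + NH₃, x = y + CO − H₂,
z = y − NH₃.  z defaults to the z-dot radical (z + 1.007825 Da) because
electron-transfer dissociation spectra conventionally display z•; plain z
is a flag away.  Multiply charged fragment m/z divides the neutral fragment
mass plus z protons by z.

Neutral-loss ions (−H₂O, −NH₃) are generated only when the fragment
contains a residue that can chemically lose the neutral (H₂O: S/T/E/D;
NH₃: R/K/N/Q) under the default `chemically_aware` mode; switching it off
attaches every requested loss to every ion.  This is a clutter/recall
trade-off with no single right answer; the default favours fewer spurious
annotations.

Annotation is a pure per-ion nearest-peak search within a tolerance
(absolute Da, or ppm evaluated at the theoretical m/z): each ion maps to at
most one peak, ties broken by higher intensity then lower m/z, while one
peak may serve several ions (isobaric fragments do collide).  The result is
therefore invariant under permutation of the ion list, and no peak
"consumption" order has to be defined.

## FASTA headers

Dialect detection is ordered grammar matching — UniProt, then legacy NCBI
gi, then IPI, then a generic first-token/remainder fallback — so specific
grammars cannot be shadowed by the fallback.  For gi headers the primary
accession is the innermost database accession and the deprecated gi number
is kept in a secondary field.  The raw header is stored verbatim and
written back byte-identically; duplicate accessions warn rather than fail
because real databases contain them.  The four grammars are an extension
point: a new dialect is a regex plus a field mapping inserted into the
precedence list.

## Identification dialects

The three adapters parse *documented minimal subsets* (defined bit-exactly
by the fixture generator, and in the `id_model` module docstring) of a
Mascot-dat-like sectioned MIME text, an X!Tandem-like XML and an OMSSA-like
CSV.  Full native formats are version-labile; the subsets carry everything
PSM-level code needs and exercise the abstraction completely.  Scores are
copied verbatim with a per-engine orientation flag — cross-engine score
calibration is explicitly not performed.  Engine identity therefore lives
in three fields (engine, score name, score orientation); everything else
(title, peptide, 1-based modifications, score value, charge, precursor
m/z, accessions, rank) is the engine-agnostic content that must be
identical whichever dialect carried it.

The OMSSA-like CSV, mirroring its namesake, has no rank column; its adapter
derives ranks by ascending E-value with lexicographic peptide tie-break.
Identical verbatim scores can only rank identically under the opposing
orientations of the three engines when each spectrum has one candidate, so
the cross-dialect convergence fixture writes one PSM per spectrum;
multi-candidate files for ranking tests are generated per engine with
orientation-consistent scores.

## Spectra, rendering, linked views

Spectra are ascending (m/z, intensity) lists; duplicate m/z values are
retained (stable sort).  MGF writing uses fixed formatting (m/z four
decimals, intensity two), making write∘read idempotent on its own output;
reading is cross-checked in the tests against an independent MGF parser.

Rendering targets static SVG/PNG export, the testable contract of an
interactive viewer.  Determinism is enforced by pinning the SVG hash salt
and stripping the embed date, so identical inputs give identical bytes.
The intensity axis spans 0..1.05× the maximum intensity inside the view
window; only windowed data is drawn.  Label collisions are resolved
deterministically: labels sorted by m/z, and a label within 1% of the
window width of its predecessor is raised one line when its peak is the
less intense.  Linked views propagate a window change to each member
exactly once (no re-entrant updates), so propagation is transitive and
loop-free; an update counter exposes this for tests.

## Data-access generation

The target engine for generated accessors is sqlite3 — embedded and
zero-configuration — with common-denominator SQL and double-quoted
identifiers.  CLOB maps to unbounded text.  `pk_autogenerated` means a
single-column INTEGER PRIMARY KEY (the rowid alias, sqlite's
auto-increment); multi-column auto-generated keys are rejected as
ill-defined.  Audit columns are matched by exact lowercase name only.
Timestamps are stamped by an injectable client clock in UTC and stored as
ISO-8601 text, so they round-trip unchanged and compare chronologically as
strings; SQL NOW() would make behaviour untestable.  Generated source is a
pure function of the descriptor (headed by a descriptor hash), emits only
bound parameters, and exposes exactly persist/update/retrieve/delete;
update refreshes `modificationdate` only and no-ops when the instance is
clean.

## Synthetic data: what it does and does not show

The fixture generators are pure functions of (seed, spec) and produce data
whose *structure* matches real files: valid dialect grammars, uniform
random sequences over the 20-residue alphabet, peak lists in range, PSMs
with plausible charges and precursor m/z consistent with the peptide mass.
They do not model fragmentation intensity, noise statistics, retention
time, isotope envelopes, or real search-engine score distributions.
Passing tests therefore demonstrate parsing, arithmetic and contract
correctness — not robustness to the messiness of instrument data or of
full native vendor formats.

Planted-ion spectra jitter each theoretical m/z by ≤0.002 Th and keep noise
peaks ≥0.05 Th from planted positions, so recovery at 0.01 Da tolerance is
guaranteed by construction; that test verifies the annotator, not a
detection limit.

## Problem sizes and defaults

The end-to-end suite uses 1,000 random peptide pairs (additivity), 500
peptides of length 2–30 (complementarity), 200 proteins ≤50 residues with
0–2 missed cleavages (digestion), 8 headers × 4 dialects (FASTA), 5 PSMs ×
3 dialects (convergence), 20 spectra with 30 noise peaks (recovery), and
20 random schemas of 1–8 columns over all five column types (CRUD) — sizes
at which every property is exercised across its combinatorial range while
the whole suite stays interactive-fast.  Fixture defaults (5 proteins of
30–120 residues, 5 spectra of 10–60 peaks, 3 PSMs, 5 schemas) are desk-
scale values chosen once for the demo corpus.
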