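# proteokit

A support toolkit for computational proteomics, for developers of proteomics
software and analysts scripting against search results.  Most proteomics
tools need the same substrate before they can do anything novel: peptide and
protein mass arithmetic, in-silico enzymatic digestion, theoretical
fragment-ion generation and spectrum annotation, FASTA databases with their
zoo of header dialects, MGF peak lists, results from several search engines,
and relational storage.  proteokit provides that substrate as a tested
library plus a thin command-line interface.

## What it computes

**Masses.**  A residue mass is the amino-acid mass minus one water, so a
neutral peptide mass is M = Σᵢ mᵢ + m(H₂O), monoisotopic or average, with
fixed-mass modifications added at N-terminus (position 0), residues (1..n)
or C-terminus (n+1).  m/z = (M + z·m_p)/z with m_p the proton mass.

**Fragmentation.**  Backbone cleavage of an n-residue peptide yields the
N-terminal a/b/c and C-terminal x/y/z series at indices 1..n−1:
b_i = prefixᵢ + m_p, y_i = suffixᵢ + m(H₂O) + m_p, a = b − CO, c = b + NH₃,
x = y + CO − H₂, z = y − NH₃ (z• = z + H, the default).  These satisfy the
complementarity identity b_i + y_{n−i} = M + 2·m_p, which the test suite
verifies to 10⁻⁶ Th on random peptides.  Annotation matches each
theoretical ion to the nearest observed peak within a Da or ppm tolerance,
ties broken by intensity then m/z.

**Digestion.**  Cleavage after a residue in the enzyme's cleave set unless
the next residue is restricted (trypsin: after K/R, not before P), with
0..m missed cleavages; verified against a brute-force substring enumerator.

**Heterogeneous formats.**  FASTA headers are auto-classified (UniProt,
legacy NCBI gi, IPI, generic fallback) into accession/description/species
fields; identification files from three search-engine dialects (Mascot-like,
X!Tandem-like, OMSSA-like minimal subsets) are sniffed and parsed into one
engine-agnostic `SpectrumMatch` model, with scores copied verbatim plus an
orientation flag.

**Data-access generation.**  A live database table is introspected (column
types, primary key, auto-generated keys, `creationdate`/`modificationdate`
audit columns) and a Python accessor class is generated exposing exactly
persist / update / retrieve / delete, with every value bound as a SQL
parameter and audit timestamps maintained by the library.

## Worked example

```sh
$ proteokit mass PEPTIDEK
PEPTIDEK        927.454928      928.0069
```

The two numbers are the neutral monoisotopic and average masses in Da:
927.454928 is the sum of the eight residue monoisotopic masses plus one
water; the average mass is ~0.55 Da heavier because it weights isotopes by
abundance.

```sh
$ proteokit fragment AGK --series by
label   series  index   charge  loss    mz
b1+     b       1       1       none    72.04439
b2+     b       2       1       none    129.06585
y1+     y       1       1       none    147.11280
y2+     y       2       1       none    204.13427
```

b1 is the alanine residue (71.03711 Da) plus a proton; y2 adds glycine,
lysine, water and a proton.  Check the identity: b1 + y2 = 276.17866 =
M(AGK) + 2 protons.

Library use mirrors the CLI:

```python
from proteokit import fragment, annotate, Tolerance, read_identifications

ions = fragment("PEPTIDEK", max_charge=2)
psms = read_identifications("results.csv")   # format auto-detected
best = [m.peptide_sequence for m in psms.matches if m.rank == 1]
```

Other subcommands: `digest` (tab-separated peptide report), `annotate`
(match a peptide's ions to an MGF spectrum), `fasta-info` (per-dialect
header counts), `plot-spectrum` (deterministic SVG/PNG export with fragment
labels), `parse-ids` (unified PSM table), `dao-gen` (accessor generation),
`fixtures` (materialise a generated demo corpus).

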