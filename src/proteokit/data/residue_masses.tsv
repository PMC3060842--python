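# Amino-acid residue masses (Da). A residue mass is the amino-acid mass minus
# one water, i.e. the mass it contributes inside a peptide chain.
# Monoisotopic values computed from the IUPAC standard atomic masses
# (CIAAW 2021); average values from IUPAC standard atomic weights.
# Columns: one-letter code <TAB> monoisotopic <TAB> average
# Rows flagged "extension" are nonstandard residues available only in
# permissive mode (selenocysteine U, pyrrolysine O).
G	57.021464	57.0519
A	71.037114	71.0788
S	87.032028	87.0782
P	97.052764	97.1167
V	99.068414	99.1326
T	101.047679	101.1051
C	103.009185	103.1388
L	113.084064	113.1594
I	113.084064	113.1594
N	114.042927	114.1038
D	115.026943	115.0886
Q	128.058578	128.1307
K	128.094963	128.1741
E	129.042593	129.1155
M	131.040485	131.1926
H	137.058912	137.1411
F	147.068414	147.1766
R	156.101111	156.1875
Y	163.063329	163.1760
W	186.079313	186.2132
U	150.953634	150.0388	extension
O	237.147727	237.3018	extension
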