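# Default amino-acid label table: 20 standard residues, alphabetical by
# 3-letter code, mapped to the integer range 4..23 (label alphabet m = 23).
# The original assignment used by the method's authors is not published;
# absolute key integers are only comparable across runs using the same table.
ALA	4
ARG	5
ASN	6
ASP	7
CYS	8
GLN	9
GLU	10
GLY	11
HIS	12
ILE	13
LEU	14
LYS	15
MET	16
PHE	17
PRO	18
SER	19
THR	20
TRP	21
TYR	22
VAL	23
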