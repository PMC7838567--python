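# Default amino-acid grouping: structurally similar residues share one label.
# Groups: {SER,THR} {ASP,GLU} {ASN,GLN} {LYS,ARG} {ILE,LEU,VAL} {PHE,TYR,TRP};
# every other residue keeps its own label. The group label is the smallest
# member label so grouped labels stay within 1..m.
ALA	4
ARG	5
ASN	6
ASP	7
CYS	8
GLN	6
GLU	7
GLY	11
HIS	12
ILE	13
LEU	13
LYS	5
MET	16
PHE	17
PRO	18
SER	19
THR	19
TRP	17
TYR	17
VAL	13
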