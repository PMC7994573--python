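# Background amino-acid frequencies (approximate natural abundances, %).
# Used as the default composition for synthetic structure sets; renormalised at load.
# resname	frequency
ALA	8.25
ARG	5.53
ASN	4.06
ASP	5.45
CYS	1.37
GLN	3.93
GLU	6.75
GLY	7.07
HIS	2.27
ILE	5.96
LEU	9.66
LYS	5.84
MET	2.42
PHE	3.86
PRO	4.70
SER	6.56
THR	5.34
TRP	1.08
TYR	2.92
VAL	6.87
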