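# United-atom partial charges (e) per residue template, heavy atoms only.
# Polar hydrogens are folded into their heavy-atom carriers, so hydrogen-bond
# donors carry net positive charge and acceptors net negative charge.
# Backbone atoms (every residue): N -0.16 (amide N + implicit H), CA +0.16,
# C +0.51, O -0.51 -> net 0.  Side-chain charges below sum to the formal charge.
# resname	atom	charge
ALA	CB	0.00
GLY	*	0.00
VAL	CB	0.00
VAL	CG1	0.00
VAL	CG2	0.00
LEU	CB	0.00
LEU	CG	0.00
LEU	CD1	0.00
LEU	CD2	0.00
ILE	CB	0.00
ILE	CG1	0.00
ILE	CG2	0.00
ILE	CD1	0.00
PRO	CB	0.00
PRO	CG	0.00
PRO	CD	0.00
PHE	CB	0.00
PHE	CG	0.00
PHE	CD1	0.00
PHE	CD2	0.00
PHE	CE1	0.00
PHE	CE2	0.00
PHE	CZ	0.00
MET	CB	0.00
MET	CG	0.05
MET	SD	-0.10
MET	CE	0.05
CYS	CB	0.10
CYS	SG	-0.10
SER	CB	0.25
SER	OG	-0.25
THR	CB	0.25
THR	OG1	-0.25
THR	CG2	0.00
TYR	CB	0.00
TYR	CG	0.00
TYR	CD1	0.00
TYR	CD2	0.00
TYR	CE1	0.00
TYR	CE2	0.00
TYR	CZ	0.25
TYR	OH	-0.25
TRP	CB	0.00
TRP	CG	0.00
TRP	CD1	0.00
TRP	CD2	0.00
TRP	NE1	0.15
TRP	CE2	-0.15
TRP	CE3	0.00
TRP	CZ2	0.00
TRP	CZ3	0.00
TRP	CH2	0.00
ASN	CB	0.00
ASN	CG	0.31
ASN	OD1	-0.55
ASN	ND2	0.24
GLN	CB	0.00
GLN	CG	0.00
GLN	CD	0.31
GLN	OE1	-0.55
GLN	NE2	0.24
ASP	CB	0.00
ASP	CG	0.10
ASP	OD1	-0.55
ASP	OD2	-0.55
GLU	CB	0.00
GLU	CG	0.00
GLU	CD	0.10
GLU	OE1	-0.55
GLU	OE2	-0.55
LYS	CB	0.00
LYS	CG	0.00
LYS	CD	0.00
LYS	CE	0.25
LYS	NZ	0.75
ARG	CB	0.00
ARG	CG	0.00
ARG	CD	0.10
ARG	NE	0.20
ARG	CZ	0.20
ARG	NH1	0.25
ARG	NH2	0.25
HIS	CB	0.00
HIS	CG	0.00
HIS	ND1	0.15
HIS	CD2	0.00
HIS	CE1	0.25
HIS	NE2	-0.40
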