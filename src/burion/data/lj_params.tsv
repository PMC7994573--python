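# Lennard-Jones parameters per element class (united heavy atoms, implicit H).
# epsilon in kcal/mol, rmin_half in Angstrom (Rmin/2; Rmin_ij = rmin_half_i + rmin_half_j).
# element	epsilon	rmin_half
C	0.120	2.10
N	0.170	1.85
O	0.120	1.70
S	0.450	2.00
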