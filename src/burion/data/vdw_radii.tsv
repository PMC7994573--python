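# van der Waals radii for solvent-accessibility (united heavy atoms, implicit H)
# element	radius_angstrom
C	1.90
N	1.70
O	1.50
S	1.80
P	1.90
SE	1.90
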