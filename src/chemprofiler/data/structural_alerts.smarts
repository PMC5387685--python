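# Structural alerts (toxicophores), partial catalog of the classical
# reactive/bioactivatable moieties screened in library triage.
# Format: family_name<TAB>SMARTS. Lines starting with # are comments.
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
quinone	O=C1[#6]=[#6]C(=O)[#6]=[#6]1
quinone_ortho	O=C1C(=O)[#6]=[#6][#6]=[#6]1
ortho_aniline	[NX3;H2,H1]c1ccccc1[NX3;H2,H1]
epoxide	C1OC1
aziridine	C1NC1
alkyl_halide	[CX4][Cl,Br,I]
aldehyde	[CX3H1](=[OX1])[#6]
beta_lactam	[NX3]1[CX3](=[OX1])[CX4][CX4]1
nitro_aromatic	c[$([NX3](=O)=O),$([NX3+](=O)[O-])]
nitroso	[#6][NX2]=[OX1]
hydrazine	[NX3;!$(N=*)][NX3;!$(N=*)]
isocyanate	[NX2]=[CX2]=[OX1]
acyl_halide	[CX3](=[OX1])[Cl,Br,I]
thiol	[#6][SX2H]
azide	[NX2]=[NX2+]=[NX1-]
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
imine_acyclic	[CX3;!R;!$([CX3][NX3])]=[NX2;!R]
michael_acceptor_nitrile	[CX3]=[CX3][CX2]#[NX1]
phosphonate_ester	[PX4](=[OX1])([OX2][#6])[OX2][#6]
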