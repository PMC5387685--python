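# Pan-assay interference (PAINS) substructure families, partial catalog.
# Format: family_name<TAB>SMARTS. Lines starting with # are comments.
# Family names follow the original PAINS nomenclature; the SMARTS are open
# re-encodings of the canonical motifs, not the original proprietary queries.
catechol_A	[OX2H]c1ccccc1[OX2H]
quinone_A	O=C1[#6]=[#6]C(=O)[#6]=[#6]1
anil_NH_alk_B	[CX4][NX3H1]c1ccccc1
sulfonamide_A	c1ccccc1[SX4](=[OX1])(=[OX1])[NX3]
azo_A	[#6][NX2]=[NX2][#6]
hzone_phenol_A	[OX2H]c1ccccc1[CX3]=[NX2][NX3]
ene_one_A	[CX3]=[CX3][CX3;!R](=[OX1])[CX3]=[CX3]
mannich_A	[OX2H]c1ccccc1[CX4][NX3]
thio_urea_A	[NX3][CX3](=[SX1])[NX3]
imine_one_A	[CX3](=[NX2])[CX3]=[OX1]
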