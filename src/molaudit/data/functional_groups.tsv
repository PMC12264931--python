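hydroxyl_any	[OX2H]
alcohol	[CX4][OX2H]
phenol	[c][OX2H]
carboxylic_acid	[CX3](=O)[OX2H1]
ester	[CX3](=O)[OX2H0][#6]
ether	[OD2]([#6])[#6]
aldehyde	[CX3H1]=O
ketone	[#6][CX3](=O)[#6]
carbonyl	[CX3]=[OX1]
amine_primary	[NX3;H2;!$(NC=O)]
amine_secondary	[NX3;H1;!$(NC=O)]([#6])[#6]
amine_tertiary	[NX3;H0;!$(NC=O)]([#6])([#6])[#6]
amide	[CX3](=O)[NX3]
nitrile	[CX2]#[NX1]
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
cc_triple_bond	C#C
cc_double_bond	C=C
aromatic_cc_bond	c:c
benzene_ring	c1ccccc1
pyridine_n	[nX2]
pyrrole_nh	[nH]
furan_o	[oX2]
thiophene_s	[sX2]
thiol	[SX2H]
thioether	[SX2]([#6])[#6]
disulfide	[SX2][SX2]
sulfoxide	[SX3]=[OX1]
sulfonyl	[SX4](=[OX1])(=[OX1])
gold_thiolate	[#16]~[#79]
fluoro	[F]
chloro	[Cl]
bromo	[Br]
iodo	[I]
imine	[CX3]=[NX2]
azo	[NX2]=[NX2]
isocyanate	[NX2]=[CX2]=[OX1]
epoxide	C1OC1
aziridine	C1NC1
urea	[NX3][CX3](=O)[NX3]
guanidine	[NX3][CX3](=[NX2])[NX3]
phosphate_p	[PX4](=[OX1])
halide_any	[F,Cl,Br,I]
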