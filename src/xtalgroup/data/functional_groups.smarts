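# Functional-group counting patterns, version 1.
# Format: name <TAB> SMARTS. Counts are unique-atom-set substructure matches.
# Patterns are mutually disambiguated: ester oxygens are not ethers, carboxylic
# acids are not esters, amide nitrogens are not amines, thiols are not
# thioethers, anhydrides are not double-counted as esters.
alcohol	[OX2H][#6;!$([CX3]=[OX1]);!$([CX3]=[SX1])]
amide	[NX3][CX3](=[OX1])
imine	[CX3]=[NX2;!$(N=O)]
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
nitrile	[NX1]#[CX2]
amine	[NX3;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[SX1]);!$([NX3](=O)=O);!$([NX3+]);!$([NX3][SX4](=O)=O);!a;!$([NX3]=*)]
ether	[OX2;H0]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]
aldehyde	[CX3H1](=[OX1])[#6,#1]
halide	[F,Cl,Br,I;$([*]~[#6])]
ketone	[#6][CX3](=[OX1])[#6]
carboxylic_acid	[CX3](=[OX1])[OX2H1]
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
ester	[CX3;!$([CX3](=[OX1])[OX2H1])](=[OX1])[OX2;H0;!$([OX2]([CX3]=[OX1])[CX3]=[OX1])][#6;!$([CX3]=[OX1])]
thiol	[SX2H]
thiocarbonyl	[CX3]=[SX1]
thioether	[SX2;H0]([#6;!$([CX3]=[SX1])])[#6;!$([CX3]=[SX1])]
sulfone	[SX4](=[OX1])(=[OX1])
phosphoric_acid	[PX4](=[OX1])([OX2])([OX2])[OX2]
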