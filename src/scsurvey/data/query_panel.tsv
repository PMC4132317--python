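# Query panel: the 33 synaptonemal-complex proteins of the model organisms.
# Columns: protein name, organism tag, source database, accession.
ASY1	At	RefSeq	NP_564896.1
ASY2	At	RefSeq	NP_194947.2
C(2)M	Dm	RefSeq	NP_609788.1
C(3)G	Dm	GenBank	ACI96726.1
CORONA	Dm	GenBank	AAF55549.2
FKBP6	Mm	Swiss-Prot	Q91XW8
HIM-3	Ce	Swiss-Prot	G5EBG0
Hop1	Sc	RefSeq	NP_012193.1
Hop1	Sp	RefSeq	NP_596448.1
Rec10	Sp	RefSeq	NP_594524.1
Red1	Sc	RefSeq	NP_013365.1
SC65	Dr	RefSeq	NP_001119910.1
SC65	Mm	GenBank	CAM23031.1
SYCE1-like	Dr	RefSeq	XP_694355.3
SYCE1	Mm	RefSeq	NP_001137237.1
SYCE2	Dr	GenBank	AAI33854.1
SYCE2	Mm	RefSeq	NP_001161718.1
SYCE3	Mm	RefSeq	NP_001156354.1
SYCP1	Dr	GenBank	AAH45503.1
SYCP1	Mm	RefSeq	NP_035646.2
SYCP2	Dr	Swiss-Prot	F1QMZ4
SYCP2	Mm	RefSeq	NP_796165.2
SYCP3-like	Dr	RefSeq	NP_001035440.1
SYCP3	Mm	RefSeq	NP_035647.2
SYP-1	Ce	Swiss-Prot	G5EGS8
SYP-2	Ce	GenBank	AAC19209.1
SYP-3	Ce	GenBank	CAB03087.2
SYP-4	Ce	RefSeq	NP_491960.1
TEX12	Af	GenBank	ACQ58790.1
TEX12	Mm	GenBank	AAH61081.1
Zip1	Sc	RefSeq	NP_010571.1
ZYP1a	At	GenBank	AAY46119.1
ZYP1b	At	GenBank	AAY46120.1
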