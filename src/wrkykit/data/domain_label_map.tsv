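# Raw domain-annotation names (Pfam/Gene3D/Superfamily style) -> controlled vocabulary.
# Users may extend this table via the label_map_path argument of read_domain_table.
TIR	TIR
TIR_2	TIR
NB-ARC	NB-ARC
NBARC	NB-ARC
LRR	LRR
LRR_1	LRR
LRR_2	LRR
LRR_3	LRR
LRR_4	LRR
LRR_5	LRR
LRR_6	LRR
LRR_8	LRR
LRRNT	LRR
LRRNT_2	LRR
WRKY	WRKY
B3	B3
NAC	NAC
NAM	NAC
CAMB	CAMB
CaM_binding	CAMB
MAPKKK	MAPKKK
Pkinase	MAPKKK
PAH	PAH
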