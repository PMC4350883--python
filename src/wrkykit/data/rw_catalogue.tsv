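# Catalogue of the 29 known chimeric R-protein/WRKY genes across flowering plants.
# Columns: name, species, gene_model, seq_id, span (1-based inclusive), rw_family, notes.
# rw_family is filled only where the source literature states the family for the
# species unambiguously; rice and sorghum members are listed under two families
# (RW5 and RW6) at species level and are therefore left unassigned here.
name	species	gene_model	seq_id	span	rw_family	notes
AtRWRKY52	Arabidopsis thaliana	AT5G45260	Chr5	18326203-18332609	RW1	RRS1, ATWRKY52, SLH1
AtRWRKY16	Arabidopsis thaliana	AT5G45050	Chr5	18176914-18181805	RW1	TTR1, ATWRKY16
AtRWRKY19	Arabidopsis thaliana	AT4G12020	Chr4	7201656-7208766	RW3	ATWRKY19, MAPKKK11; only RW3 member
AlRWRKY1	Arabidopsis lyrata	AL915586	scaffold_8	2126189-2132181	RW1
AlRWRKY2	Arabidopsis lyrata	AL915663	scaffold_8	2768079-2773021	RW1
AlRWRKY3	Arabidopsis lyrata	AL915648	scaffold_8	2623905-2628796	RW1
SbRWRKY1	Sorghum bicolor	SOBIC.002G104400	Chr02	12369911-12381876	unassigned	species listed under both RW5 and RW6
SbRWRKY2	Sorghum bicolor	Sobic.008G174100	Chr08	53517353-53522939	unassigned	species listed under both RW5 and RW6
SbRWRKY3	Sorghum bicolor	Sobic.002G168300	Chr02	52695615-52704484	unassigned	species listed under both RW5 and RW6
CrRWRKY1	Capsella rubella	CARUBV10025744M	scaffold_8	1365382-1370221	RW1
CrRWRKY2	Capsella rubella	CARUBV10025742M	scaffold_8	1163667-1169265	RW1
OsjRWRKY1	Oryza sativa japonica	LOC_Os07g17230	Chr7	10149830-10159829	unassigned	FgenesH prediction different; species listed under both RW5 and RW6
OsiRWRKY1	Oryza sativa indica	BGIOSGA035675	Chromosome_11	21830082-21837218	unassigned	species listed under both RW5 and RW6
OsjRWRKY2	Oryza sativa japonica	gi|108864659	Chr11	27783900-27793499	unassigned	Retrotransposon at 3 prime end
FvRWRKY1	Fragaria vesca	MRNA21370	LG7	18263740-18277966	RW2
FvRWRKY2	Fragaria vesca	MRNA13368	LG7	22236162-22242036	RW2
FvRWRKY3	Fragaria vesca	MRNA03900ALT	LG7	9804380-9813690	RW2
FvRWRKY4	Fragaria vesca	MRNA16678alt	LG6	802048-808355	RW2
AtaRWRKY1	Aegilops tauschii	R7VZB5	Scaffold219315		RW6	no span printed
GmRWRKY1	Glycine max	Glyma05g29921.1	Gm05	35364051-35374699	RW4
GrRWRKY1	Gossypium raimondii	Gorai.008G201000	Chr08	48587929-48599304	RW7	WRKY domains truncated, difficult to classify
GrRWRKY2	Gossypium raimondii	Gorai.008G200800	Chr08	48660141-48668419	RW7
TcRWRKY1	Theobroma cacao	Thecc1EG006109	scaffold_2	820964-828678	RW8
TcRWRKY2	Theobroma cacao	Thecc1EG006103	scaffold_2	805474-814178	RW8
TcRWRKY3	Theobroma cacao	Thecc1EG006116t1	scaffold_2	845249-851848	RW8
HvRWRKY1	Hordeum vulgare	MLOC_74974.5	Chr5	483720745-483727238	RW6
SiRWRKY1	Setaria italica	Si028710m.g	scaffold_2	26415481-26421105	RW6
PvRWRKY1	Panicum virgatum	Pavir.J20878sg0.contig22731/9	CL19939Contig1		RW5	no span printed
FvRWRKY5	Fragaria vesca	MRNA21370	LG7	18263740-18277966	RW2	Tandem repeat with FvRWRKY1
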