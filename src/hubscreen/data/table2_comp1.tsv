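# Table 2, component-1 column — hub-bottleneck nodes of the larger main connected
# component of the common-genes PPI network (18 genes). Curated by hand from the
# source table; raw run preserved verbatim below:
# TP53MYCCTNNB1SRCSMAD2AKT1HSPA4SMAD4FOSALBTNFRSF1AHRASPPARGCDKN2ALGALS3CDH1CCND1MSH2
# rank	symbol	description
1	TP53	Cellular tumor antigen p53
2	MYC	Myc proto-oncogene protein
3	CTNNB1	Catenin beta-1
4	SRC	Proto-oncogene tyrosine-protein kinase Src
5	SMAD2	Mothers against decapentaplegic homolog 2
6	AKT1	RAC-alpha serine/threonine-protein kinase
7	HSPA4	Heat shock 70 kDa protein 4
8	SMAD4	Mothers against decapentaplegic homolog 4
9	FOS	Proto-oncogene c-Fos
10	ALB	Serum albumin
11	TNFRSF1A	Tumor necrosis factor receptor superfamily member 1A
12	HRAS	GTPase HRas
13	PPARG	Peroxisome proliferator-activated receptor gamma
14	CDKN2A	Cyclin-dependent kinase inhibitor 2A
15	LGALS3	Galectin-3
16	CDH1	Cadherin-1
17	CCND1	G1/S-specific cyclin-D1
18	MSH2	DNA mismatch repair protein Msh2
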