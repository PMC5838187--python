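# Table 5 — final hub-bottleneck nodes of the common-genes PPI network (20 genes),
# the component-aware merge of Table 2's two columns (Table 1 rows 20-29 excluded,
# SNW1 added). Curated by hand from the source table; raw run preserved verbatim:
# TP53MYCCTNNB1SRCSMAD2AKT1HSPA4SMAD4FOSCASS1ALBTNFRSF1AHRASPPARGCDKN2ALGALS3CCND1CDH1MSH2SNW1
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
10	CASS1	Cas scaffolding protein family member 1
11	ALB	Serum albumin
12	TNFRSF1A	Tumor necrosis factor receptor superfamily member 1A
13	HRAS	GTPase HRas
14	PPARG	Peroxisome proliferator-activated receptor gamma
15	CDKN2A	Cyclin-dependent kinase inhibitor 2A
16	LGALS3	Galectin-3
17	CCND1	G1/S-specific cyclin-D1
18	CDH1	Cadherin-1
19	MSH2	DNA mismatch repair protein Msh2
20	SNW1	SNW domain-containing protein 1
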