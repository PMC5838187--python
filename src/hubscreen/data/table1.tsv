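# Table 1 — hub-bottleneck nodes of the combined common-genes PPI network.
# 29 rows; CDKN2A appears twice (rows 15 and 28), so 28 unique symbols after
# normalization. Curated by hand from the source table, whose symbol column was a
# single concatenated cell; raw run preserved verbatim below:
# TP53MYCCTNNB1SRCSMAD2AKT1HSPA4SMAD4FOSCASS1ALBTNFRSF1AHRASPPARGCDKN2ALGALS3CCND1CDH1MSH2KRASVDRBCL2L1MSH6EGFSMAD7CD44VEGFACDKN2ACAT
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
20	KRAS	GTPase KRas
21	VDR	Vitamin D3 receptor
22	BCL2L1	Bcl-2-like protein 1
23	MSH6	DNA mismatch repair protein Msh6
24	EGF	Pro-epidermal growth factor
25	SMAD7	Mothers against decapentaplegic homolog 7
26	CD44	CD44 antigen
27	VEGFA	Vascular endothelial growth factor A
28	CDKN2A	Cyclin-dependent kinase inhibitor 2A
29	CAT	Catalase
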