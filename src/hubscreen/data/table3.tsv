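# Table 3 — hub-bottleneck nodes of the colon-adenocarcinoma (COAC) PPI network
# (11 genes). Curated by hand from the source table; raw run preserved verbatim:
# ALBTP53PRDM10AKT1CTNNB1EGFRMYCHRASSRCMAPK3EGF
# rank	symbol	description
1	ALB	Serum albumin
2	TP53	Cellular tumor antigen p53
3	PRDM10	PR domain zinc finger protein 10
4	AKT1	RAC-alpha serine/threonine-protein kinase
5	CTNNB1	Catenin beta-1
6	EGFR	Epidermal growth factor receptor
7	MYC	Myc proto-oncogene protein
8	HRAS	GTPase HRas
9	SRC	Proto-oncogene tyrosine-protein kinase Src
10	MAPK3	Mitogen-activated protein kinase 3
11	EGF	Pro-epidermal growth factor
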