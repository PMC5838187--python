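# Table 4 — hub-bottleneck nodes of the ulcerative-colitis (UC) PPI network
# (25 genes). Curated by hand from the source table; raw run preserved verbatim:
# ALBIL6AKT1TP53TNFSRCIL8VEGFAEGFMAPK3IL10MYCIL1BIL4TLR4IL2FOSJUNIL13TGFB1CSF2ICAM1MAPK8STAT3IFNG
# rank	symbol	description
1	ALB	Serum albumin
2	IL6	Interleukin-6
3	AKT1	RAC-alpha serine/threonine-protein kinase
4	TP53	Cellular tumor antigen p53
5	TNF	Tumor necrosis factor
6	SRC	Proto-oncogene tyrosine-protein kinase Src
7	IL8	Interleukin-8
8	VEGFA	Vascular endothelial growth factor A
9	EGF	Pro-epidermal growth factor
10	MAPK3	Mitogen-activated protein kinase 3
11	IL10	Interleukin-10
12	MYC	Myc proto-oncogene protein
13	IL1B	Interleukin-1 beta
14	IL4	Interleukin-4
15	TLR4	Toll-like receptor 4
16	IL2	Interleukin-2
17	FOS	Proto-oncogene c-Fos
18	JUN	Transcription factor AP-1
19	IL13	Interleukin-13
20	TGFB1	Transforming growth factor beta-1
21	CSF2	Granulocyte-macrophage colony-stimulating factor
22	ICAM1	Intercellular adhesion molecule 1
23	MAPK8	Mitogen-activated protein kinase 8
24	STAT3	Signal transducer and activator of transcription 3
25	IFNG	Interferon gamma
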