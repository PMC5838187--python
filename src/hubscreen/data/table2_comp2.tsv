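# Table 2, component-2 column — hub-bottleneck nodes of the smaller main connected
# component of the common-genes PPI network (4 genes). Curated by hand from the
# source table; raw run preserved verbatim below:
# TP53SNW1CTNNB1CASS1
# rank	symbol	description
1	TP53	Cellular tumor antigen p53
2	SNW1	SNW domain-containing protein 1
3	CTNNB1	Catenin beta-1
4	CASS1	Cas scaffolding protein family member 1
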