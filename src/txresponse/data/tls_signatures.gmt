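TLS_9_gene	tertiary lymphoid structure signature (differential-expression derived)	CD79B	CD1D	CCR6	LAT	SKAP1	CETP	EIF1AY	RBP5	PTGDS
TLS_7_gene_hallmark	tertiary lymphoid structure hallmark signature	CCL19	CCL21	CXCL13	CCR7	CXCR5	SELL	LAMP3
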