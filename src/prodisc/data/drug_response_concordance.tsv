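gene	histotype	response	discriminable	established
BRAF	SKCM	Y	Y	1
ERBB2	BRCA	Y	Y	1
ERBB2	STAD	Y	Y	1
ERBB2	LUAD	Y	Y	0
ERBB2	PAAD	N	N	0
EGFR	LUAD	Y	Y	1
FGFR1	LUSC	Y	Y	1
FGFR1	COAD	N	N	0
FGFR1	UCEC	N	Y	0
FGFR1	SKCM	Y	Y	1
KRAS	LUAD	Y	Y	0
KRAS	UCEC	N	Y	0
KRAS	COAD	N	N	1
KRAS	STAD	N	N	0
KRAS	LUAD	Y	Y	0
MET	GBM	N	Y	0
MET	SKCM	N	N	0
MET	STAD	Y	N	0
MET	BRCA	N	Y	0
MET	KIRP	Y	Y	0
MET	KIRC	N	N	1
MET	OV	N	Y	0
MET	LUAD	Y	Y	0
PIK3CA	BLCA	Y	N	0
PIK3CA	HNSC	N	N	0
PIK3CA	STAD	N	Y	0
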