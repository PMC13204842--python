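CD138_POS	CD138-positive transcriptional program (protein-coding, up in tumor-positive phenotype)	S100A7	CD24	GLYATL2
CD138_NEG	CD138-negative transcriptional program (protein-coding, up in tumor-negative phenotype)	RERG	SLC39A6	NAT1	SCUBE2	PIP	NPY1R	SLC7A2	GRIA2	FSIP1	PTPRT	SERPINA3
SNORNA_MODULE	snoRNAs enriched in the tumor-positive/stroma-negative phenotype	SNORA21	SNORA1	SNORA25	SNORD14D	SNORA70	SNORA14B	SNORA22C	SNORD111	SNORD111B	SNORA21B	SNORA67
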