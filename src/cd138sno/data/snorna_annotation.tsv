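sno_symbol	host_gene	box_type	target_rrna	positions	modification	family_status
SNORA21	RPL23	H/ACA	28S	4401,4470	Ψ	family
SNORA21B	RPL23	H/ACA	28S	4401,4470	Ψ	family
SNORA1	TAF1D	H/ACA	28S	4441	Ψ	single
SNORA25	TAF1D	H/ACA	28S	801,814	Ψ	single
SNORD14D	HSPA8	C/D	18S	462	2'-O-Me	single
SNORA70	RPL10	H/ACA	18S	1232,1692	Ψ	single
SNORA14B	TOMM20	H/ACA	18S	681,966	Ψ	single
SNORA22C	CCT6P3	H/ACA	18S	918	Ψ	single
SNORD111	SF3B3	C/D	28S	3823	2'-O-Me	family
SNORD111B	SF3B3	C/D	28S	3823	2'-O-Me	family
SNORA67	EIF4A1	H/ACA	18S	1445	Ψ	single
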