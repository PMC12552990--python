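probe_id	chrom	pos	island_relation	gene	in_region	epicv2	epicv1	m450k	m27k	qc_flags
cg13533245	chr9	27561767	open_sea	C9orf72	1	1	0	0	0
cg01126010	chr9	27564906	open_sea	C9orf72	1	1	1	0	0
cg15843044	chr9	27567156	open_sea	C9orf72	1	1	1	0	0
cg01861827	chr9	27569287	open_sea	C9orf72	1	1	1	0	0
cg13958452	chr9	27571486	shelf	C9orf72	1	1	1	1	0
cg13533303	chr9	27571819	shore	C9orf72	1	1	0	0	0
cg13533310	chr9	27572615	shore	C9orf72	1	1	0	0	0
cg13533317	chr9	27572969	shore	C9orf72	1	1	0	0	0
cg13533352	chr9	27573249	shore	C9orf72	1	1	0	0	0
cg13533354	chr9	27573281	shore	C9orf72	1	1	0	0	0
cg13533361	chr9	27573369	shore	C9orf72	1	1	0	0	0
cg13533362	chr9	27573379	shore	C9orf72	1	1	0	0	0
cg01589155	chr9	27573534	shore	C9orf72	1	1	1	0	0
cg05151778	chr9	27573550	shore	C9orf72	1	1	1	0	0
cg05990720	chr9	27573652	island	C9orf72	1	1	1	1	0
cg23074747	chr9	27573819	island	C9orf72	1	1	1	1	1
cg13533397	chr9	27573885	island	C9orf72	1	1	0	0	0
cg11613875	chr9	27573891	island	C9orf72	1	1	1	1	1
cg03854581	chr9	27573968	island	C9orf72	1	1	1	0	0
cg13533404	chr9	27573982	island	C9orf72	1	1	0	0	0
cg14363787	chr9	27573988	island	C9orf72	1	1	1	1	0
cg13533410	chr9	27574186	shore	C9orf72	1	1	0	0	0
cg01589701	chr9	27574385	shore	C9orf72	1	1	1	0	0
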