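term_id	term_name	genes
GO:0002376	immune system process	TNF,IL8,CR1,CLU,CCR2,PICALM,CHRNB2
GO:0016192	vesicle-mediated transport	PICALM,SORL1,APOE,BIN1,LDLR,CLU
GO:0016044	cellular membrane organization	SORL1,APOE,PICALM,BIN1,LDLR
GO:0006066	alcohol metabolic process	CHRNB2,SORL1,APOE,TNF,LDLR
GO:0006869	lipid transport	SORL1,APOE,LDLR,CLU,TNF
GO:0008202	steroid metabolic process	SORL1,APOE,TNF,LDLR
GO:0008203	cholesterol metabolic process	APOE,CLU,LDLR,SORL1
GO:0008219	cell death/apoptosis	APOE,TNF,CLU
GO:0016477	cell migration	IL8,APOE,TNF
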