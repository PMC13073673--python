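SASP_AND_INTEREST	SASP factors and senescence genes of interest	IL6	CXCL8	IL1A	IL1B	IL11	IL15	IL18	IL32	AREG	EREG	HGF	FGF2	FGF7	VEGFA	VEGFC	IGF1	IGF2	IGF1R	IGF2R	IGFBP2	IGFBP3	IGFBP4	IGFBP5	IGFBP6	IGFBP7	PAPPA	MMP1	MMP2	MMP3	MMP9	MMP10	MMP12	TIMP1	TIMP2	SERPINE1	SERPINE2	SERPINB2	PLAU	PLAT	CCL2	CCL3	CCL4	CCL5	CCL7	CCL8	CCL13	CCL17	CCL19	CCL20	CCL21	CCL26	CXCL1	CXCL2	CXCL3	CXCL5	CXCL10	CXCL12	CX3CL1	CSF1	CSF2	CSF3	TNF	TNFRSF1A	TNFRSF1B	TNFRSF10C	ICAM1	ICAM3	TGFB1	TGFB2	INHBA	GDF15	SPP1	RARRES2	CCN2	SFRP2	WNT16	DKK1	MIF	CTSB	COL1A1	CD55	LMNB1	EGF	EGFR	FAS	CD9	ANG	AXL	NRG1	PGF	KITLG	MIF4GD	STC1	STC2	SEMA3F	PTGES	CST4	CCL16	CCL25	CXCL13	CXCL16	CDKN1A	CDKN2A	TP53	SCAMP4	B2M
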