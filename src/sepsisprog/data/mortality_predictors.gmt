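Duke_up	higher in non-survivors	TRIB1	CKS2	MKI67	POLD3	PLK1
Duke_down	lower in non-survivors	TGFBI	LY86	CST3	CBFA2T3	RCBTB2	TST	CX3CR1	CD5	MTMR11	CLEC10A	EMR3	DHRS7B	CEACAM8
Sage_LR_up	higher in non-survivors	CFD	DDIT4	DEFA4	IFI27	IL1R2	IL8	MAFF	OCLN	RGS1
Sage_LR_down	lower in non-survivors	AIM2	APH1A	CCR2	EIF5A	GSTM1	HIST1H3H	NT5E	RAB40B	VNN3
Sage_RF_up	higher in non-survivors	B4GALT4	BPI	CD24	CEP55	CTSG	DDIT4	G0S2	MPO	MT1G	NDUFV2	PAM	PSMA6	SEPP1
Sage_RF_down	lower in non-survivors	ABCB4	CTSS	IKZF2	NT5E
Stanford_up	higher in non-survivors	DEFA4	CD163	PER1	RGS1	HIF1A	SEPP1	C11orf74	CIT
Stanford_down	lower in non-survivors	LY86	TST	OR52R1	KCNJ2
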