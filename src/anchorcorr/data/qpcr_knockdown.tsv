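tissue	gene	rel_value_shr	predicted_sign	p_value
colon	BTG2	1.25	negative	1.5e-02
lung	DAPK2	1.35	negative	6.0e-12
lung	GADD45B	1.63	negative	2.6e-02
lung	SATB1	2.82	negative	4.3e-04
thyroid	ABCA1	1.68	negative	2.8e-02
thyroid	B3GALT4	1.32	negative	2.0e-03
thyroid	PTEN	1.29	negative	4.3e-02
colon	CCT3	0.62	positive	2.9e-03
colon	DKC1	0.60	positive	8.3e-04
colon	HSP90AB1	0.82	positive	2.4e-02
colon	MYC	0.57	positive	6.7e-03
colon	ODC1	0.80	positive	1.3e-02
colon	RRM2	0.66	positive	4.0e-02
liver	DDB1	0.63	positive	3.6e-02
liver	HN1	0.65	positive	1.3e-03
liver	ILF2	0.79	positive	5.7e-04
liver	RAN	0.75	positive	1.3e-02
lung	BUB3	0.82	positive	8.2e-03
lung	USP14	0.74	positive	2.7e-03
thyroid	ATR	0.47	positive	5.6e-03
colon	ACLY	1.40	positive	3.7e-05
thyroid	TSC2	2.18	positive	1.4e-05
colon	CDK1	0.50	negative	7.3e-07
colon	SPPL2A	0.38	negative	3.5e-02
colon	TUBG1	0.43	negative	8.5e-05
liver	EHHADH	0.61	negative	4.4e-02
liver	CYP4F2	0.70	negative	3.2e-02
lung	STARD8	0.66	negative	7.5e-03
lung	UNC13A	4.73	positive	8.2e-06
thyroid	PPAP2A	0.63	negative	2.8e-02
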