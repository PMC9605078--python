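compound	rotb	hba	hbd	esol_logs	esol_class	tpsa	clogp	bioavailability_score	lipinski	lipinski_violations	gia
Captopril	4	3	1	-1.14	Very soluble	96.41	0.62	0.56	Yes	0	High
PL	6	4	3	0.66	Highly soluble	78.43	0.04	0.55	Yes	0	High
DF	8	6	4	0.83	Highly soluble	129.72	-0.69	0.56	Yes	0	High
GP	3	4	2	1.25	Highly soluble	83.63	-1.17	0.55	Yes	0	High
AF	6	4	3	0.39	Highly soluble	92.42	0.05	0.55	Yes	0	High
PR	9	5	6	1.94	Highly soluble	140.33	-1.59	0.55	Yes	1	Low
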