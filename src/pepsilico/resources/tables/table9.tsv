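fragment	prediction	hydrophobicity	hydrophilicity	charge	pi	mw
PL	Non-toxic	0.23	-0.9	0	5.88	228.31
DF	Non-toxic	-0.05	0.25	-1	3.8	280.29
GP	Non-toxic	0.04	0	0	5.88	172.20
AF	Non-toxic	0.43	-1.5	0	5.88	236.28
PR	Non-toxic	-0.92	1.5	1	10.11	271.33
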