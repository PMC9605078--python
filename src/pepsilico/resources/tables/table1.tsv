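sample	score	sequence
flower	0.96	GPPGPQWPLDF
flower	0.94	GPPGPRGPTGRMG
flower	0.94	GPGGPGPGM
flower	0.93	APDMAFPR
flower	0.92	GGFPGGPG
flower	0.92	GPGMMGP
flower	0.90	GPPGASGPLGIAGSM
flower	0.90	GPSGPPGP
internal organs	0.96	GPPGPQWPLDF
internal organs	0.94	GEPFPKF
internal organs	0.93	APDMAFPR
internal organs	0.92	PGGPGPGM
internal organs	0.92	GPGMMGP
internal organs	0.90	DPIFFPS
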