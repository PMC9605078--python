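sample	peptide	fragmentation	fragment_spans	active_fragments	active_spans	bioactivity
flower	GPPGPQWPLDF	GPPGPQW-PL-DF	1-7;8-9;10-11	PL;DF	8-9;10-11	ACE inhibitor
flower	GPPGPRGPTGRMG	GPPGPR-GPTGR-M-G	1-6;7-11;12-12;13-13			No Antioxidant or ACE inhibitory activity
flower	GPGGPGPGM	_				_
flower	APDMAFPR	APDM-AF-PR	1-4;5-6;7-8	PR;AF	7-8;5-6	ACE inhibitor
flower	GGFPGGPG	GGF-PGGPG	1-3;4-8			No Antioxidant or ACE inhibitory activity
flower	GPGMMGP	GPGM-M-GP	1-4;5-5;6-7	GP	6-7	ACE inhibitor
flower	GPPGASGPLGIAGSM	GPPGASGPL-GIAGSM	1-9;10-15			No Antioxidant or ACE inhibitory activity
flower	GPSGPPGP	_				_
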