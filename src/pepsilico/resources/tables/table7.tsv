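sample	peptide	fragmentation	fragment_spans	active_fragments	active_spans	bioactivity
internal organs	GPPGPQWPLDF	GPPGPQW-PL-DF	1-7;8-9;10-11	PL;DF	8-9;10-11	ACE inhibitor
internal organs	GEPFPKF	GEPF-PK-F	1-4;5-6;7-7			No Antioxidant or ACE inhibitory activity
internal organs	APDMAFPR	APDM-AF-PR	1-4;5-6;7-8	PR;AF	7-8;5-6	ACE inhibitor
internal organs	PGGPGPGM	_				_
internal organs	GPGMMGP	GPGM-M-GP	1-4;5-5;6-7	GP	6-7	ACE inhibitor
internal organs	DPIFFPS	DPIF-F-PS	1-4;5-5;6-7			No Antioxidant or ACE inhibitory activity
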