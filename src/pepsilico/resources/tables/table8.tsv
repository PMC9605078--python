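peptide	samples	active_fragments	locations	locations_corrected	erratum	dht_percent	ae	w
GPPGPQWPLDF	flower, internal organs	PL;DF	8-9;10-1	8-9;10-11	printed 10-1 is a typo for 10-11	20	0.18	0.25
GPGMMGP	flower, internal organs	GP	6-7			33.33	0.14	0.14
APDMAFPR	flower, internal organs	AF;PR	5-6;7-8			28.57	0.25	0.33
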