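sample	sequence	name	fragment	locations	locations_corrected	erratum
internal organs	GPPGPQWPLDF	ACE inhibitor from Alaskan pollack skin	GP	1-2;4-5
internal organs	GPPGPQWPLDF	ACE inhibitor from Alaskan pollack skin	PL	8-9
internal organs	GPPGPQWPLDF	ACE inhibitor	PG	3-4
internal organs	GPPGPQWPLDF	ACE inhibitor from wheat gliadin	GPP	1-3
internal organs	GPPGPQWPLDF	ACE inhibitor	PP	2-3
internal organs	GPPGPQWPLDF	ACE inhibitor	PQ	5-6
internal organs	GPPGPQWPLDF	ACE inhibitor	DF	10-11
internal organs	GEPFPKF	ACE inhibitor	FP	4-5
internal organs	GEPFPKF	ACE inhibitor from Tricholoma giganteum	GEP	1-3
internal organs	GEPFPKF	ACE inhibitor	GE	1-2
internal organs	GEPFPKF	ACE inhibitor	KF	6-7
internal organs	GEPFPKF	ACE inhibitor	PFP	3-5
internal organs	APDMAFPR	ACE inhibitor	FP	7-8	6-7	printed locations shifted +1
internal organs	APDMAFPR	ACE inhibitor	PR	8-9	7-8	printed locations shifted +1
internal organs	APDMAFPR	ACE inhibitor	AFP	6-8	5-7	printed locations shifted +1
internal organs	APDMAFPR	ACE inhibitor	AF	6-7	5-6	printed locations shifted +1
internal organs	APDMAFPR	ACE inhibitor	AP	2-3	1-2	printed locations shifted +1
internal organs	APDMAFPR	ACE inhibitor	DM	4-5	3-4	printed locations shifted +1
internal organs	PGGPGPGM	ACE inhibitor from Alaskan pollack skin	GP	3-4;5-6
internal organs	PGGPGPGM	ACE inhibitor	GM	7-8
internal organs	PGGPGPGM	ACE inhibitor	GG	2-3
internal organs	PGGPGPGM	ACE inhibitor	PG	1-2;4-5;6-7
internal organs	GPGMMGP	ACE inhibitor from Alaskan pollack skin	GP	2-3;7-8	1-2;6-7	printed locations shifted +1
internal organs	GPGMMGP	ACE inhibitor	GM	4-5	3-4	printed locations shifted +1
internal organs	GPGMMGP	ACE inhibitor	MG	6-7	5-6	printed locations shifted +1
internal organs	GPGMMGP	ACE inhibitor	PG	3-4	2-3	printed locations shifted +1
internal organs	GPGMMGP	ACE inhibitor	MM	5-6	4-5	printed locations shifted +1
internal organs	GPGMMGP	ACE inhibitor	MGP	6-8	5-7	printed locations shifted +1
internal organs	DPIFFPS	ACE inhibitor	FP	5-6
internal organs	DPIFFPS	ACE inhibitor	IF	3-4
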