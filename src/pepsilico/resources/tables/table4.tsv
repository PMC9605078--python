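sample	sequence	name	fragment	locations	locations_corrected	erratum
flower	GPPGPQWPLDF	ACE inhibitor from Alaskan pollack skin	GP	1-2;4-5
flower	GPPGPQWPLDF	ACE inhibitor from Alaskan pollack skin	PL	8-9
flower	GPPGPQWPLDF	ACE inhibitor	PG	3-4
flower	GPPGPQWPLDF	ACE inhibitor from wheat gliadin	GPP	1-3
flower	GPPGPQWPLDF	ACE inhibitor	PP	2-3
flower	GPPGPQWPLDF	ACE inhibitor	PQ	5-6
flower	GPPGPQWPLDF	ACE inhibitor	DF	10-11
flower	GPPGPRGPTGRMG	ACE inhibitor	PR	5-6
flower	GPPGPRGPTGRMG	ACE inhibitor from Alaskan pollack skin	GP	1-2;4-5;7-8
flower	GPPGPRGPTGRMG	ACE inhibitor	GR	10-11
flower	GPPGPRGPTGRMG	ACE inhibitor	MG	12-13
flower	GPPGPRGPTGRMG	ACE inhibitor	TG	9-10
flower	GPPGPRGPTGRMG	ACE inhibitor	PG	3-4
flower	GPPGPRGPTGRMG	ACE inhibitor from wheat gliadin	GPP	1-3
flower	GPPGPRGPTGRMG	ACE inhibitor	PT	8-9
flower	GPPGPRGPTGRMG	ACE inhibitor	PP	2-3
flower	GPPGPRGPTGRMG	ACE inhibitor	RG	6-7
flower	GPGGPGPGM	ACE inhibitor from Alaskan pollack skin	GP	1-2;4-5;6-7
flower	GPGGPGPGM	ACE inhibitor	GM	8-9
flower	GPGGPGPGM	ACE inhibitor	GG	3-4
flower	GPGGPGPGM	ACE inhibitor	PG	2-3;5-6;7-8
flower	APDMAFPR	ACE inhibitor	FP	6-7
flower	APDMAFPR	ACE inhibitor	PR	7-8
flower	APDMAFPR	ACE inhibitor	AFP	5-7
flower	APDMAFPR	ACE inhibitor	AF	5-6
flower	APDMAFPR	ACE inhibitor	AP	1-2
flower	APDMAFPR	ACE inhibitor	DM	3-4
flower	GGFPGGPG	ACE inhibitor	FP	4-5	3-4	printed locations shifted +1
flower	GGFPGGPG	ACE inhibitor from Alaskan pollack skin	GP	7-8	6-7	printed locations shifted +1
flower	GGFPGGPG	ACE inhibitor	GF	3-4	2-3	printed locations shifted +1
flower	GGFPGGPG	ACE inhibitor	GG	2-3;6-7	1-2;5-6	printed locations shifted +1
flower	GGFPGGPG	ACE inhibitor	PG	5-6;8-9	4-5;7-8	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor	GM	4-5	3-4	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor	MG	6-7	5-6	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor	PG	3-4	2-3	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor	MM	5-6	4-5	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor	MGP	6-8	5-7	printed locations shifted +1
flower	GPGMMGP	ACE inhibitor from Alaskan pollack skin	GP		1-2;6-7	row omitted in print; required by the release-descriptor arithmetic
flower	GPPGASGPLGIAGSM	ACE inhibitor from Alaskan pollack skin	GPL	7-9
flower	GPPGASGPLGIAGSM	ACE inhibitor from Alaskan pollack skin	PLG	8-10
flower	GPPGASGPLGIAGSM	ACE inhibitor from Alaskan pollack skin	GP	1-2;7-8
flower	GPPGASGPLGIAGSM	ACE inhibitor from Alaskan pollack skin	PL	8-9
flower	GPPGASGPLGIAGSM	ACE inhibitor from soy hydrolysate	IA	11-12
flower	GPPGASGPLGIAGSM	ACE inhibitor	GI	10-11
flower	GPPGASGPLGIAGSM	ACE inhibitor	GA	4-5
flower	GPPGASGPLGIAGSM	ACE inhibitor	AG	12-13
flower	GPPGASGPLGIAGSM	ACE inhibitor	GS	13-14
flower	GPPGASGPLGIAGSM	ACE inhibitor	SG	6-7
flower	GPPGASGPLGIAGSM	ACE inhibitor	LG	9-10
flower	GPPGASGPLGIAGSM	ACE inhibitor	PG	3-4
flower	GPPGASGPLGIAGSM	ACE inhibitor from wheat gliadin	GPP	1-3
flower	GPPGASGPLGIAGSM	ACE inhibitor	PP	2-3
flower	GPPGASGPLGIAGSM	ACE inhibitor	LGI	9-11
flower	GPPGASGPLGIAGSM	ACE inhibitor	SGP	6-8
flower	GPPGASGPLGIAGSM	ACE inhibitor	AGS	12-14
flower	GPSGPPGP	ACE inhibitor from Alaskan pollack skin	GP	1-2;4-5;7-8
flower	GPSGPPGP	ACE inhibitor	SG	3-4
flower	GPSGPPGP	ACE inhibitor	PG	6-7
flower	GPSGPPGP	ACE inhibitor from wheat gliadin	GPP	4-6
flower	GPSGPPGP	ACE inhibitor	PP	5-6
flower	GPSGPPGP	ACE inhibitor	SGP	3-5
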