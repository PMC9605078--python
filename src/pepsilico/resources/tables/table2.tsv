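sample	sequence	name	activity	fragment	location	location_corrected	erratum
flower	GPPGPQWPLDF	peptide from buckwheat	antioxidative	WPL	7-9
flower	GPPGPQWPLDF	Antioxidative peptide	antioxidative	GPP	1-3
flower	GPPGPRGPTGRMG	Antioxidative peptide	antioxidative	GPP	1-3
flower	GPGGPGPGM	_	_	_
flower	APDMAFPR	_	_	_
flower	GGFPGGPG	_	_	_
flower	GPGMMGP	Antioxidative peptide	antioxidative	MM	5-6	4-5	printed location shifted +1
flower	GPPGASGPLGIAGSM	Antioxidative peptide	antioxidative	GPP	1-3
flower	GPSGPPGP	Antioxidative peptide	antioxidative	GPP	4-6
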