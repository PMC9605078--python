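sample	sequence	name	activity	fragment	location	location_corrected	erratum
internal organs	GPPGPQWPLDF	Peptide from buckwheat	antioxidative	WPL	7-9
internal organs	GPPGPQWPLDF	Antioxidative peptide	antioxidative	GPP	1-3
internal organs	GEPFPKF	_	_	_
internal organs	APDMAFPR	_	_	_
internal organs	PGGPGPGM	_	_	_
internal organs	GPGMMGP	Antioxidative peptide	antioxidative	MM	5-6	4-5	printed location shifted +1
internal organs	DPIFFPS	_	_	_
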