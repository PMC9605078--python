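fragment	activity	name	provenance
WPL	antioxidative	peptide from buckwheat	antioxidant profile, flower + internal organs
GPP	antioxidative	Antioxidative peptide	antioxidant profile, flower + internal organs
MM	antioxidative	Antioxidative peptide	antioxidant profile, flower + internal organs
GP	ACE-inhibitor	ACE inhibitor from Alaskan pollack skin	ACE profile, flower + internal organs
PL	ACE-inhibitor	ACE inhibitor from Alaskan pollack skin	ACE profile, flower + internal organs
GPL	ACE-inhibitor	ACE inhibitor from Alaskan pollack skin	ACE profile, flower
PLG	ACE-inhibitor	ACE inhibitor from Alaskan pollack skin	ACE profile, flower
GPP	ACE-inhibitor	ACE inhibitor from wheat gliadin	ACE profile, flower + internal organs
IA	ACE-inhibitor	ACE inhibitor from soy hydrolysate	ACE profile, flower
GEP	ACE-inhibitor	ACE inhibitor from Tricholoma giganteum	ACE profile, internal organs
PG	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
PP	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
PQ	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
DF	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
PR	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
GR	ACE-inhibitor	ACE inhibitor	ACE profile, flower
MG	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
TG	ACE-inhibitor	ACE inhibitor	ACE profile, flower
PT	ACE-inhibitor	ACE inhibitor	ACE profile, flower
RG	ACE-inhibitor	ACE inhibitor	ACE profile, flower
GM	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
GG	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
FP	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
AFP	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
AF	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
AP	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
DM	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
GF	ACE-inhibitor	ACE inhibitor	ACE profile, flower
MM	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
MGP	ACE-inhibitor	ACE inhibitor	ACE profile, flower + internal organs
GI	ACE-inhibitor	ACE inhibitor	ACE profile, flower
GA	ACE-inhibitor	ACE inhibitor	ACE profile, flower
AG	ACE-inhibitor	ACE inhibitor	ACE profile, flower
GS	ACE-inhibitor	ACE inhibitor	ACE profile, flower
SG	ACE-inhibitor	ACE inhibitor	ACE profile, flower
LG	ACE-inhibitor	ACE inhibitor	ACE profile, flower
LGI	ACE-inhibitor	ACE inhibitor	ACE profile, flower
SGP	ACE-inhibitor	ACE inhibitor	ACE profile, flower
AGS	ACE-inhibitor	ACE inhibitor	ACE profile, flower
GE	ACE-inhibitor	ACE inhibitor	ACE profile, internal organs
KF	ACE-inhibitor	ACE inhibitor	ACE profile, internal organs
PFP	ACE-inhibitor	ACE inhibitor	ACE profile, internal organs
IF	ACE-inhibitor	ACE inhibitor	ACE profile, internal organs
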