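# Core-reaction -> iJN1463 reaction mapping for MFA-derived bounds.
# Comma-separated GEM ids; a '-' prefix flips the sign convention (the GEM
# reaction's positive direction opposes the core reaction's).  Multi-id
# entries are bounded as a summed group (MDH + MDH2 per the combined
# malate-dehydrogenase rule).  This table is the implementer's
# reconstruction of the reaction correspondence and is meant to be edited
# alongside the model version in use.
core_reaction	gem_reactions
upt	-EX_xyl__D_e
pgi	-PGI
zwf	G6PDH2r
gnd	GND
edd	EDD
eda	EDA
tkt1	TKT1
tkt2	TKT2
tal	TALA
rpe	RPE
rpi	-RPI
fba	-FBA
fbp	FBP
tpi	TPI
emp	ENO
pyk	PYK
pdh	PDH
ppc	PPC
maeB	ME2
gltA	CS
acn	ACONTa
icd	ICDHyr
akgdh	AKGDH
sdh	SUCDi
fum	FUM
mdh	MDH,MDH2
aceA	ICL
glcB	MALS
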