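# Ground-truth net fluxes, molar % of xylose uptake (uptake = 100).
# Xylose-grown P. putida EM42 PD310 core network; authored fixture
# consistent with the measured flux statements for this strain.
# uptake_rate_abs = 1.45
reaction	net_pct	sd_pct	exch_pct
upt	100.0000	2.50	0.0
xylA	100.0000	2.50	0.0
xylB	100.0000	2.50	0.0
rpe	-10.6088	0.30	0.0
rpi	45.2906	1.13	0.0
tkt1	44.7952	1.12	5.0
tkt2	44.5960	1.11	5.0
tal	44.7952	1.12	5.0
pgi	89.0000	2.22	5.0
zwf	87.8690	2.20	0.0
gnd	34.6818	0.87	0.0
edd	53.1872	1.33	0.0
eda	53.1872	1.33	0.0
fba	0.0000	0.30	0.0
fbp	0.0000	0.30	0.0
tpi	0.0000	0.30	0.0
emp	97.7120	2.44	0.0
pyk	74.5942	1.86	0.0
pdh	121.1521	3.03	0.0
ppc	12.0000	0.30	0.0
pyc	1.0000	0.30	0.0
maeB	10.0000	0.30	0.0
gltA	87.6644	2.19	0.0
acn	87.6644	2.19	0.0
icd	74.8542	1.87	0.0
akgdh	68.9017	1.72	0.0
sdh	81.7119	2.04	0.0
fum	81.7119	2.04	0.0
mdh	84.5221	2.11	0.0
aceA	12.8102	0.32	0.0
glcB	12.8102	0.32	0.0
dG6P	1.1310	0.30	0.0
dF6P	0.3912	0.30	0.0
dR5P	0.4954	0.30	0.0
dE4P	0.1992	0.30	0.0
dGAP	0.0712	0.30	0.0
dPEP	11.1178	0.30	0.0
dPYR	15.6292	0.39	0.0
dAcCoA	20.6775	0.52	0.0
dOAA	9.8577	0.30	0.0
dAKG	5.9526	0.30	0.0
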