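# Core carbon network of engineered P. putida EM42 growing on D-xylose:
# exogenous isomerase route (XylA/XylB) feeding the EDEMP cycle
# (non-oxidative PPP + ED pathway + partial EMP), TCA cycle with
# glyoxylate shunt, and anaplerotic/cataplerotic exchange.
# Lumping: Zwf+Pgl as one G6P->6PG step; Gap+Pgk+Pgm+Eno as one GAP->PEP step.
# The CO2 pool is treated as an unbalanced, unlabeled reservoir.
@substrate XYL.ext
@uptake upt
@unbalanced XYL.ext CO2
@met XYL 5 D-xylose (cytosolic)
@met XLU 5 D-xylulose
@met X5P 5 xylulose 5-phosphate
@met Ru5P 5 ribulose 5-phosphate
@met R5P 5 ribose 5-phosphate
@met S7P 7 sedoheptulose 7-phosphate
@met E4P 4 erythrose 4-phosphate
@met F6P 6 fructose 6-phosphate
@met G6P 6 glucose 6-phosphate
@met 6PG 6 6-phosphogluconate
@met KDPG 6 2-keto-3-deoxy-6-phosphogluconate
@met FBP 6 fructose 1,6-bisphosphate
@met DHAP 3 dihydroxyacetone phosphate
@met GAP 3 glyceraldehyde 3-phosphate
@met PEP 3 phosphoenolpyruvate
@met PYR 3 pyruvate
@met AcCoA 2 acetyl-CoA
@met CIT 6 citrate
@met ICIT 6 isocitrate
@met AKG 5 2-ketoglutarate
@met SUC 4 succinate
@met FUM 4 fumarate
@met MAL 4 malate
@met OAA 4 oxaloacetate
@met GLX 2 glyoxylate

upt: XYL.ext (abcde) -> XYL (abcde) ! XylE
xylA: XYL (abcde) -> XLU (abcde) ! XylA
xylB: XLU (abcde) -> X5P (abcde) ! XylB
rpe: Ru5P (abcde) <-> X5P (abcde) ! Rpe
rpi: Ru5P (abcde) <-> R5P (abcde) ! RpiA
tkt1: X5P (abcde) + R5P (fghij) <-> S7P (abfghij) + GAP (cde) ! Tkt
tkt2: X5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde) ! Tkt
tal: S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg) ! Tal
pgi: F6P (abcdef) <-> G6P (abcdef) ! Pgi
zwf: G6P (abcdef) -> 6PG (abcdef) ! Zwf-Pgl
gnd: 6PG (abcdef) -> Ru5P (bcdef) + CO2 (a) ! Gnd
edd: 6PG (abcdef) -> KDPG (abcdef) ! Edd
eda: KDPG (abcdef) -> PYR (abc) + GAP (def) ! Eda
fba: DHAP (abc) + GAP (def) <-> FBP (abcdef) ! Fba
fbp: FBP (abcdef) -> F6P (abcdef) ! Fbp
tpi: DHAP (abc) <-> GAP (cba) ! TpiA
emp: GAP (abc) -> PEP (abc) ! Gap-Pgk-Pgm-Eno
pyk: PEP (abc) -> PYR (abc) ! Pyk
pdh: PYR (abc) -> AcCoA (bc) + CO2 (a) ! Pdh
ppc: PEP (abc) + CO2 (d) -> OAA (abcd) ! Ppc
pyc: PYR (abc) + CO2 (d) -> OAA (abcd) ! Pyc
maeB: MAL (abcd) -> PYR (abc) + CO2 (d) ! MaeB
gltA: OAA (abcd) + AcCoA (ef) -> CIT (efbacd) ! GltA
acn: CIT (abcdef) -> ICIT (abcdef) ! Acn
icd: ICIT (abcdef) -> AKG (fecba) + CO2 (d) ! Icd
akgdh: AKG (abcde) -> SUC (bcde) + CO2 (a) ! 2Kgd
sdh: SUC (abcd) -> FUM (abcd|dcba) ! Sdh
fum: FUM (abcd) <-> MAL (abcd|dcba) ! FumC
mdh: MAL (abcd) <-> OAA (abcd) ! Mdh
aceA: ICIT (abcdef) -> SUC (abcd) + GLX (ef) ! AceA
glcB: GLX (ab) + AcCoA (cd) -> MAL (badc) ! GlcB

# biomass precursor drains (lumped, no atom maps)
dG6P: G6P -> ! drain
dF6P: F6P -> ! drain
dR5P: R5P -> ! drain
dE4P: E4P -> ! drain
dGAP: GAP -> ! drain
dPEP: PEP -> ! drain
dPYR: PYR -> ! drain
dAcCoA: AcCoA -> ! drain
dOAA: OAA -> ! drain
dAKG: AKG -> ! drain
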