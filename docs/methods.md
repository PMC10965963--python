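# Methods

## Core network and atom maps

The packaged core model (`data/edemp_core.net`) covers xylose uptake and
isomerization (XylE/XylA/XylB), the non-oxidative PPP, the lumped
oxidative step Zwf–Pgl (G6P → 6PG), the Gnd decarboxylation back into
Ru5P, the ED pair Edd/Eda, the gluconeogenic Fbp/Fba/TpiA segment, a
lumped lower-glycolysis step Gap–Pgk–Pgm–Eno (GAP → PEP), pyruvate
metabolism (Pyk, Pdh), anaplerosis/cataplerosis (Ppc, Pyc, MaeB), the TCA
cycle, and the glyoxylate shunt (AceA, GlcB). Ten lumped drains withdraw
biomass precursors.

Carbon transitions follow the canonical central-carbon maps of the
¹³C-MFA literature: transketolase moves C1–C2 units, transaldolase C1–C3
units, Eda cleaves KDPG into pyruvate (C1–C3) and GAP (C4–C6), citrate
synthase places the acetyl moiety on the distal arm so that the CO₂
released by isocitrate dehydrogenase derives from the oxaloacetate C1
carboxyl, and the symmetric intermediates succinate and fumarate scramble
orientation 50/50 (encoded as equal-weight atom-map variants,
`(abcd|dcba)`). Reversibility (Pgi, Rpe, RpiA, Tkt, Tal, TpiA, Fba, FumC,
Mdh) follows the thermodynamic conventions of published *P. putida*
central-carbon models. The CO₂ pool is treated as an unbalanced,
unlabeled reservoir: decarboxylations discard label into it and
carboxylations (Ppc, Pyc) draw unlabeled carbon from it. A balanced,
labeled CO₂ pool can be modeled by declaring CO₂ balanced in the network
file and adding an outflow; the machinery handles it like any other pool,
at the cost of realism elsewhere (dissolved CO₂ exchanges quickly with
the headspace, which the unlabeled-reservoir treatment approximates).

The reference flux distribution (`data/edemp_fluxes.tsv`) is an authored
steady-state flux map for xylose-grown cells: its free coordinates are
Pgi = 89, Ppc = 12, MaeB = 10, Pyc = 1, Fbp = 0 (% of uptake), and every
dependent flux follows from closing the node balances with biomass drains
scaled to µ = 0.08 h⁻¹ at q_S = 1.45 mmol gCDW⁻¹ h⁻¹. The resulting map
has Edd = 53.2 (majority of carbon into the ED pathway), Gnd = 34.7
(more than a third recycled to the PPP), an active glyoxylate shunt
(12.8), and negligible Fbp/Fba/TpiA flux. Standard errors in the table
are nominal two-replicate values (max(0.3, 2.5%) of the flux) used by the
FBA bound construction.

## EMU simulation and the isotopomer oracle

`simulate_mids` implements the standard EMU decomposition: backward
traversal from each observed fragment collects, per EMU size k, a linear
balance A(v)·X_k = B(v)·Y_k whose inputs are tracer EMUs and convolutions
of smaller-size solutions. Matrices are assembled from precomputed index
lists, so one forward simulation of the packaged network costs ~1 ms and
the decomposition is reused across an entire fit. Reversible reactions
contribute both lanes with rates max(net, 0)+exch and max(−net, 0)+exch.

Pools with zero turnover at the supplied flux vector (e.g. the
FBP/DHAP loop when Fbp = Fba = TpiA = 0) would make the size-k systems
singular; they are pinned to an arbitrary unlabeled MID, which is exact
because every downstream term referencing them carries zero flux. Genuine
singularities still raise, naming the dead nodes.

`brute_force_mids` is the validation oracle: the full positional
isotopomer balance over every pool's 2ⁿ states, solved by fixed-point
substitution (the packaged core network enumerates to ~900 states; a
guard refuses above ~2²⁰). Each pool is renormalized to a probability
distribution after every sweep — the balance is bilinear in the pools, so
the sum mode is unstable under iteration and must be projected out; the
true solution has sum exactly 1, so the projection is exact. The oracle
shares nothing with the EMU path beyond the parsed network.

Isotope effects are ignored and carbon labels are binary (¹²C/¹³C);
tracer impurity enters through `TracerSpec.purity` (0.99 for the
99%-pure 1,2-¹³C xylose), and natural isotope abundance is handled
downstream in `mid_processing`, not in the labeling simulation.

A caveat on tracer mixtures: the EMU system is linear in the *input EMU
MIDs*, so the MID under a tracer mixture equals the simulation with the
mixed input — but it does **not** equal the average of separate
pure-tracer experiments whenever condensation reactions recombine
molecules of different tracer species (cross terms). The averaging
identity holds only on recombination-free routes and is tested there.

## Measured fragments

The packaged measurement spec uses TBDMS-derivatized proteinogenic amino
acids (Ala, Gly, Ser, Val, Thr, Asp, Glu as [M-57], plus [M-159] for
Ala/Asp/Glu) mapped onto their biosynthetic precursors (pyruvate,
3-phosphoglycerate ≡ PEP under the lumping, oxaloacetate,
2-ketoglutarate), and intact IC-MS MIDs of X5P, R5P, S7P, F6P, G6P and
6PG — the sugar phosphates being what resolves the cyclic upper fluxes.
Valine is expressed as the convolution of two pyruvate EMUs (C1–C3 and
C2–C3), which is exactly the EMU treatment of its condensation origin and
avoids adding biosynthesis reactions to S. Phenylalanine is omitted: its
precursors (PEP, E4P) are already sensed directly, so it adds bookkeeping
and no identifiability. Fragment formulas for the correction matrices are
derived as amino acid + n×TBDMS − C₄H₉ ([M-57]) or − C₇H₁₅O₂Si ([M-159]),
and [M−H]⁻ for the IC-MS species.

## MID correction

The observed mass distribution is the backbone-label MID pushed through a
column-stochastic convolution matrix: natural heavy-isotope envelopes of
all non-backbone atoms (IUPAC 2013 abundances, pinned in
`CorrectionConfig`) convolved with natural ¹³C over the unlabeled
backbone positions. Correction inverts this by non-negative least
squares, renormalizes, and reports the residual (with a quality warning
above 0.02). Unlabeled biomass carried in with the inoculum is removed as
mid → (mid − f·e₀)/(1−f); f is a user input (default 0, documented
example 0.05) estimated from the inoculum/ harvest OD ratio. Both maps
are linear, so their order is immaterial.

## Flux fitting

Free net fluxes for the core network are Pgi, Ppc, MaeB, Pyc and Fbp —
interpretable coordinates that complete [S; uptake; drains] to full rank
(an automatic rank-greedy selection covers other networks). Exchange
fluxes are fitted for Tkt1, Tkt2, Tal and Pgi through the bounded
transform ρ = exch/(exch + uptake), ρ ∈ [0, 0.9]; the fixture's default
exchanges are 5% of uptake there and 0 elsewhere (exchange fluxes are
not observable under this tracer in the reference flux state — the upper
sugar MIDs are degenerate — so their fitted values are reported but not
interpreted). Biomass drains are fixed from a standard Gram-negative
precursor-demand vector (mmol/gCDW) scaled by µ/q_S.

The objective is Σ((sim − meas)/σ)² with an absolute SD floor of 0.003
mass fractions, plus hinge penalties (weight 30 per % of violation) that
keep dependent irreversible fluxes non-negative; candidate vectors are
clipped to the feasible boundary for simulation. Optimization is
bound-constrained trust-region least squares (`scipy.optimize.
least_squares`, trf) from 50 seeded multi-starts (log-uniform over the
free-flux box), followed by a high-precision polish; identical seeds give
bit-identical results. Degrees of freedom are Σ(len(MID) − 1) − p,
counting one constraint per fragment for the sum-to-one normalization.

Goodness of fit is the central 95% chi-square band. Note a calibration
caveat: the synthetic noise model (additive Gaussian, clipped at 0,
renormalized) violates the iid assumption — clipping at the many exactly
zero mass fractions produced by the 1,2-¹³C tracer and per-fragment
renormalization correlate residuals — so full-pipeline SSRs are heavier
tailed than χ²(dof) even when the model is correct. The chi-square
calibration itself is verified on an interior-MID testbed where the
assumptions hold.

Confidence intervals use parameter continuation: the target net flux is
made a free coordinate (swapping the basis if needed), stepped away from
its optimum with geometric step growth while all other parameters are
re-optimized from warm starts, until the profile SSR crosses
SSR_opt + χ²₁(0.95) = 3.84; the crossing is then located by bisection
(default resolution 0.05% of uptake). Profile re-optimizations use
3-point finite-difference Jacobians because the feasibility boundary
creates one-sided kinks that defeat forward differences. Unbounded
directions are flagged as open. On an exactly linear measurement map the
continuation interval reproduces ±1.96·SE from the analytic curvature.

## Genome-scale comparison

`gem_fba` is a thin scientific layer over cobrapy (GLPK backend). The
xylose surgery adds xyl__D_e/p/c and xylu__D_c plus EX_xyl__D_e, XYLtex,
XYLt2pp (proton symport), XYLI1 and XYLK, and deletes GCD; added
reactions are elementally balanced (C/H/O/P checked from formulas).
MFA-derived bounds are mean ± 1.96·SE in absolute units
((%/100)·1.45 mmol gCDW⁻¹ h⁻¹); multi-reaction entries (MDH+MDH2) become
one linear constraint on the summed flux. The shipped core→iJN1463
mapping table is the implementer's reconstruction of the reaction
correspondence (sign conventions flip where BIGG orientations oppose the
core model, e.g. PGI, RPI, FBA) and is meant to be edited alongside the
model version.

Biomass maximization uses GLPK; flux-dependent summaries (NADPH/NADH
generation, CO₂ release) are reported at the parsimonious-FBA tie-break
because alternate optima would otherwise make them arbitrary, and an
FVA-based envelope of the production-side sums over the optimal face is
attached to expose the remaining degeneracy. "Generation" of a cofactor
is production-side only at the solved flux sign (consumption excluded);
net CO₂ is gross production minus fixation over non-boundary reactions.
The published iJN1463 numbers require the BIGG download; the packaged toy
reconstruction exercises the identical code path, with a forced
decarboxylating bypass reproducing the qualitative signature of Gnd
cycling (lower growth, higher CO₂ and NADPH formation).

## Growth kinetics

µ_max is the steepest slope of ln OD over a rolling window that passes an
R² screen; the lag is the intersection of that tangent with the initial
ln OD baseline; Y_X/S = ΔCDW/ΔS with CDW = 0.39·OD (gravimetric
conversion for these strains) and q_S = µ/(Y_X/S·M_xylose),
M_xylose = 150.13 g/mol. Window defaults were chosen by a scan of
estimator bias on the synthetic generator across the relevant growth
scenarios: at 15-min sampling a 5-point window has ~6% slope SE at 1%
multiplicative noise and the max-over-windows selection then inflates
µ_max by 5–8%, so the defaults are window = 13 points (3.25 h) and
min R² = 0.97, giving |bias| ≤ 1% at the fast-growth scenario
(µ 0.21 h⁻¹, 1% noise) and ≤ 5% for the slow, noisier one (µ 0.11 h⁻¹,
2% noise). Both are configurable; OD below 0.01 is excluded from log
fits.

## Synthetic generators

`generate_mid_dataset` adds additive Gaussian noise (default SD 0.004
per mass fraction — typical GC-MS MID repeatability), clips at zero,
renormalizes, and records the nominal SD; a multiplicative mode exists.
The growth generator produces lagged-logistic OD curves (default od0
0.05, capacity 3.5 OD, 15-min sampling, 1% multiplicative noise) with
yield-coupled substrate depletion from 5 g/L. Defaults mirror the batch
cultivation conditions of the strains under study (evolved-strain
scenario µ = 0.21 h⁻¹, lag 3.4 h; parental scenario µ = 0.11 h⁻¹, lag
10 h). What the generators do **not** emulate: chromatographic artifacts,
detector saturation, fragment-dependent noise, diauxie, death phase, or
condensation/evaporation drifts in plate readers — so passing recovery
tests demonstrates correctness of the estimators under the stated noise
model, not robustness to every failure mode of real instruments.

## Problem sizes

The test suite and acceptance script run at desk scale: the EMU/oracle
cross-checks use toy networks of ≤ 300 isotopomer states (100 random flux
draws each) plus the full ~900-state core network; recovery fits use 50
multi-starts (noise-free reference run) or 4–8 (noisy replicates); CI
calibration uses 20 seeded replicates. The whole suite completes in a few
minutes on one CPU.

## Known limitations

* Atom maps and the reference flux values are authored (the study's
  figure-level data are not machine-readable); they satisfy every stated
  quantitative property of the measured flux map but are not the INCA
  point estimates.
* Exchange fluxes are essentially unidentifiable under the 1,2-¹³C
  tracer in the reference flux state; the fit reports them without
  uncertainty claims.
* The chi-square goodness-of-fit band is approximate under the clipped,
  renormalized noise model (see above).
* The unlabeled-CO₂ reservoir slightly mislabels Ppc/Pyc products when
  intracellular CO₂ is in fact partially labeled.
* The core→iJN1463 mapping and the NADPH/NADH reaction sets are
  reconstructions; users comparing against a specific model release
  should review both tables.
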