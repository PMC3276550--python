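# Methods

## The model

`spinesim` simulates dopamine-activated PKA signaling in a segment of medium
spiny projection neuron (MSPN) dendrite carrying spines, as a stochastic
reaction–diffusion system on a mesh of well-mixed subvolumes. Dopamine binds
D1 receptors coupled through Gαolf to adenylate cyclase type 5; cAMP loads the
PKA holoenzyme (two pre-paired sites per regulatory lobe), releasing catalytic
subunits that phosphorylate DARPP-32 Thr34 (a PP1 inhibitor), GluA1 Ser845 and
PDE10 (whose activity PKA enhances). Cdk5 maintains a large phospho-Thr75
DARPP-32 pool that inhibits PKA. Calcium enters through imposed influx trains,
is buffered by calbindin and extruded by PMCA/NCX pumps, inhibits the cyclase,
and acts through calmodulin on PDE1, calcineurin (which dephosphorylates
Thr34 and Ser845) and CaMKII (which phosphorylates Ser831). The network
comprises 109 species and 94 kinetic-scheme rows that expand to 211 elementary
mass-action reactions (reversible rows → forward+backward; enzyme rows
E+S⇌ES⇀E+P → bind/unbind/catalyze). Twenty-two conserved moieties (receptor,
G-protein subunits, cyclase, phosphatases, kinases, DARPP-32, GluA1, calcium,
buffers, pumps) lie exactly in the left null space of the stoichiometric
matrix and anchor both testing and the reporting groups.

Units: concentrations nM, volumes µm³, time s, diffusion µm²/s. One nM·µm³ is
0.602 molecules.

### Rate-law conventions

* Bimolecular rate constants are nM⁻¹s⁻¹ as printed; per-subvolume stochastic
  propensity constants are c = kf/(0.602·V).
* Rows written `X + 2 L ⇌ XL₂` (calmodulin's two site pairs, the two cAMP
  sites per PKA lobe) bind a pre-paired ligand couple: the rate law is
  bimolecular, kf·[X]·[L], with two ligands consumed per event. This choice is
  fixed by the printed kf units and verified against the tabulated basal state
  (it reproduces basal PKA·cAMP₂ within a few percent, where a [L]² law is off
  by ~50×).
* Self-reactions `A + A → …` have flux kf·[A]² and propensity c·n(n−1)/2 with
  c = 2kf/(0.602·V).
* The two D1-receptor activation routes (Da binding before vs after G-protein
  association) share the ternary complex and its single 20 s⁻¹ catalytic step;
  the expansion de-duplicates it. The printed PMR (microscopic-reversibility)
  rates close their thermodynamic loops to machine precision, which the test
  suite verifies for the receptor square and every holoenzyme–target square.

### Morphology

The reference short mesh is a 7.75 µm dendrite (0.6 × 0.4 µm² cross-section)
of 310 cuboids (62 axial slices × 5 lanes of 0.12 µm; outer lanes form the
submembrane shell, matching the submembrane:cytosol ratio of a cylinder with a
70 nm shell within 5%) carrying four spines: 0.1 µm cylindrical slices — three
neck slices (0.2 µm ⌀; variants with 0 or 10 slices), two head slices and one
PSD slice (0.6 µm ⌀). Diffusion is 2-D in the dendritic sheet, 1-D up the
spine; finite-volume couplings k = D·A/(V·d) satisfy detailed balance by
construction. The long mesh for gradient runs is a 22.8 µm dendrite of 342
cuboids (0.2 × 0.2 × 0.4 µm³, 3×2 cross-section) with 12 spines at ~1/µm.

Anchoring configurations place the D1R/G/AC complex and the PKA pool either in
the spine heads or in focal dendritic submembrane patches. There is one patch
beneath each spine, each with the volume of one spine head and carrying that
spine's quota of the anchored pools, so local and global anchored
concentrations are identical in every configuration (a property the analysis
depends on and the tests assert). A single shared patch holding the whole pool
would quadruple local concentrations and, through the bimolecular G–cyclase
coupling, invert the colocalization ordering. The "uniform PKA" (Ht31 mimic)
configuration spreads the PKA pool over the whole morphology.

### Initial state

Basal concentrations come from the packaged tables. Cytosolic pools populate
the entire morphology; PDE10 occupies the submembrane and spine subvolumes
(or everything, in the uniform variant); anchored receptor/G/cyclase pools
stay out of the PSD while PKA pools and GluA1 include it. Two quantities the
source tables omit are set once: the PMCA/NCX totals balance the constitutive
CaOut→Ca leak exactly at basal calcium (flux split equally between the pumps),
and GluA1 is 80 receptors per PSD, inside the experimentally reported range —
Ser845 status is reported as a percentage, so results are insensitive to the
absolute count. Integer counts are drawn by expectation-preserving stochastic
rounding (floor + Bernoulli on the fraction), so sub-single-molecule
concentrations average correctly across subvolumes and seeds.

Deterministic scenario runs start from a 400 s basal relaxation of the
configuration (the slowest basal pool, GluA1 phosphorylation, needs a few
hundred seconds to equilibrate); stimuli then start at t = 50 s of the
recorded run and analysis windows (50–350 s etc.) are measured from run start.

### Stimulation

* Phasic dopamine: five 1 s, 1 µM elevations, 20 s apart. In
  volume-transmission mode (D_Da = 150 µm²/s) the transient is a uniform
  clamp; in gradient mode (D slowed 3× to 50 µm²/s) dopamine is injected at
  the first spine's PSD at a rate calibrated by one sparse linear solve of the
  (linear) dopamine diffusion+export subsystem so the release-site peak is
  still 1 µM.
* Calcium tetanus: 100 pulses × 3 ms × 125 molecules/ms into two PSDs with
  10 ms gaps (37,500 ions per stimulated spine over ~1.3 s).
* Bath application: a sustained uniform clamp (e.g. 10 µM dopamine, 600 nM
  calcium) for validation runs.

## Engines

### Stochastic (tau-leap reaction–diffusion)

Per fixed step (default 5 µs), every subvolume draws one Poisson count of
reaction firings from its cached total propensity — exact by superposition of
the per-reaction Poisson processes — and attributes firings to reactions in
proportion to cached propensities; caches update incrementally as counts
change, so quiescent subvolumes cost one draw per step. Diffusion draws, per
(subvolume, diffusible species), one aggregate binomial for leavers
(p = Σ hop probabilities, each capped below 0.1 per coupling — exceeding the
cap aborts with the offending coupling named) and splits them multinomially
across couplings; moves are buffered and applied together, so per-species
totals are conserved exactly. If a leap would drive a count negative, the
subvolume's step is redrawn at halved dt (≤5 times) and then falls back to an
exact SSA for that subvolume-step. Clamps reset counts at the start of every
step; injections add Poisson-distributed molecules. Runs are bit-reproducible
for a fixed seed. An adaptive mode selects the step from the standard
mean/variance leap bounds (ε = 0.03) for well-mixed ensembles, where no
diffusion cap applies.

### Deterministic (mass-action ODE)

The same elementary reactions integrate as stiff ODEs (BDF, rtol 10⁻⁶, atol
10⁻³ nM — several species sit at single-molecule concentrations) with an
analytic Jacobian: dense for the pooled well-mixed system, sparse
(block reaction Jacobian + kron(G, diag(D)) diffusion part) for the
compartmental system. Stimulus pulse edges split the integration into
segments; clamps hold species algebraically, injections are square-wave
sources. The engine serves as the verification oracle for the stochastic
engine (20-trial tau-leap means agree within 3 SE on the well-mixed full
network) and as the desk-scale substitute for trial-mean readouts.

## Readouts

"PhosphoThr34 DARPP-32" (and Thr75) sum every species carrying the
phosphosite, free or complexed, divided by the reporting volume. GluA1 is
reported as percent of the receptor pool phosphorylated on Ser845 (Ser831
status ignored), including phosphatase-bound forms. "PKA activity" is free
catalytic subunit integrated over the recording window (50–350 s); complexes
with substrates do not count. Spatial profiles average each axial dendritic
slice over a window (cAMP 50–150 s; phospho-proteins 100–250 s) and are fit
with C₀·e^(−x/λ) + b by bounded nonlinear least squares; for cAMP, which
decays to basal within the mesh, b is pinned to the far-end level, while
phospho-protein profiles (λ comparable to the dendrite length) keep b free;
profiles with <2% relative range are flagged non-identifiable. The
colocalization analysis is an OLS regression of PKA activity on local cAMP
(at the PKA anchoring site) and a 0/1 colocalization flag across runs.
Between-condition comparisons across seeds use mean ± SEM (Welch's t-test
where a p-value is needed).

## Desk-scale presets

Reference-fidelity stochastic runs (500 s at 5 µs steps) are multi-day;
scenario presets therefore substitute:

* deterministic spatial runs on axially coarsened meshes — the short mesh at
  31 slices × 3 lanes (117 subvolumes, identical volumes and submembrane
  fractions) and the long mesh with the cross-section collapsed (57 axial
  subvolumes + 12 spines) — for all trial-mean readouts (validation folds,
  anchoring comparisons, gradient fits);
* short fixed-step stochastic runs on the full 310-cuboid mesh where the
  readout is a peak or variability statistic (the calcium tetanus runs its
  first 45 pulses, by which the per-pulse peak has plateaued);
* for the activity regression, a reduced two-spine mesh (single-lane dendrite,
  one-subvolume necks, merged head+PSD) whose gentler couplings admit 40 µs
  steps, with 1 µM dopamine transients and windows of tens of seconds. The
  reduced ensembles preserve the analysis structure — local cAMP significant,
  the colocalization flag not — but R² is sensitive to the window length
  because PKA activation integrates over minutes; the full-length stochastic
  design remains the definitive version of this analysis.
* the 100 Hz calcium train is smoothed to its mean influx rate in the
  deterministic pairing runs (the readouts integrate over 300 s, far longer
  than the 13 ms pulse period).

Every desk scenario completes in minutes on one CPU; the registry documents a
budget per scenario.

## Numerical and design choices

* Reversible rows are stored as irreversible pairs (uniform propensity
  machinery). Reactions then diffusion within each step; at 5 µs the operator
  splitting error is negligible.
* Negativity policy (halve-and-redraw, then exact SSA) preserves leap accuracy
  at small-copy-number boundaries rather than clipping.
* Diffusion destination sampling is multinomial across couplings, preventing
  over-draining of a subvolume within a step.
* The well-mixed reduction of this model is *not* faithful for absolute
  responses: cyclase activation is bimolecular between colocalized anchored
  pools, and pooling dilutes their local concentrations ~10-fold (the pooled
  basal steady state settles to ~2 nM cAMP vs ~30 nM spatially). Well-mixed
  runs are used only as the stochastic-vs-ODE cross-check, never as a
  substitute for the anchored-configuration experiments; validation runs use
  the spatial engine.
* Under bath application the anchoring layout is immaterial (agonist is
  clamped everywhere), so validation runs use the standard spine-anchored
  configuration.

## What the generator does and does not emulate

Synthetic inputs reproduce the study's stimulation statistics: reward-like
phasic dopamine transients, LTP-protocol calcium influx, bath agonist
application. They do not model dopamine transporter uptake (gradient mode
slows diffusion instead), NMDA receptor gating (influx is imposed), ERK/STEP/
CK1 pathways, or receptor desensitization. Passing tests therefore demonstrate
internal consistency of the published kinetic scheme and its spatial
organization, not a fit to new experimental data.

## Limitations

* Desk presets trade stochastic trial structure for deterministic means;
  variability claims are exercised only in reduced stochastic runs.
* The anchoring-disruption (uniform PKA) effect on phosphoThr34 DARPP-32 comes
  out near 15% here versus ~30% in the reference stochastic study (identical
  at both mesh resolutions, so not a discretization artifact): diffusible
  DARPP-32 homogenizes Thr34 phosphorylation across the morphology — the same
  mechanism this model identifies as erasing PKA gradients — so redistributing
  PKA costs pThr34 less than it costs the PSD-fixed GluA1 readout (~25%,
  in line with the reference).
* The tabulated basal state is not an exact fixed point of the kinetic scheme
  (the source model's own basal values were simulation outputs); a 400 s
  relaxation defines the operative basal state, and slow pools (PDE10
  phosphorylation, Thr75 turnover) continue to drift by a few percent over
  hundreds of seconds.
* picoSD surface densities for dendritic anchoring are retained as provenance
  only; anchored totals follow the equal-local-and-global-concentration rule.
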