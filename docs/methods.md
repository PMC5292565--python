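# Methods

## Scope and model structure

`vegfnet` implements a rule-based model of VEGF signaling through VEGFR2 to
ERK1/2 and cytosolic calcium, together with its inhibition by TSP1 acting
through CD47.  The model has three coupled layers:

1. **Receptor network** (`rules`, `modelio`).  Molecules are site-graphs:
   VEGF (two receptor-binding arms plus an NRP1 site), VEGFR2 (ligand site
   L, coupling site C, a lumped phosphotyrosine Y with states U/P, and a
   CD47-association site), VEGFR1 (L, C, an NRP1 site), NRP1 (one site that
   binds VEGF or VEGFR1 competitively), CD47 (a TSP1 site and a VEGFR2
   site; SIRPα is lumped into CD47), and TSP1 (one CD47 site).  Interaction
   rules — ligand binding, ligand-mediated and ligand-independent
   dimerization, NRP1 coupling, CD47 pre-association, TSP1 engagement,
   autophosphorylation/dephosphorylation, and whole-complex trafficking —
   are iterated to a fixed point, enumerating every reachable species and
   mass-action reaction.  The packaged rule set generates 792 species and
   8233 directed reactions (5006 when a reversible pair is counted once).
2. **ERK cascade** (`cascade`).  A coarse-grained closed-form layer:
   pVEGFR2 phosphorylates PLCγ by a Michaelis–Menten catalytic step
   (rate = k·[pVEGFR2]·[PLCγ]/(Km+[PLCγ])); pPLCγ proxies the DAG/IP3
   branch (IP3 source for the calcium module, PKC activation as a weak
   trigger arm into Raf).  The dominant ERK route is a calcium-gated
   positive feedback loop: pERK phosphorylates SphK1; calcium-loaded CIB1
   (a cooperative myristoyl switch) translocates phospho-SphK1 to the
   membrane; membrane SphK1 produces S1P; S1P activates Ras
   (rate = k·[S1P]/([S1P]+Km), catalytic and scaled by the remaining
   RasGDP fraction so the pool stays nonnegative); Ras drives
   Raf → MEK → ERK.  The ERK cycle uses saturable kinase and phosphatase
   velocities (zero-order ultrasensitivity), which together with the
   feedback loop produces genuinely switch-like, near-binary ERK
   activation.
3. **Calcium module** (`calcium`).  IP3-gated ER release, an ER leak,
   SERCA and plasma-membrane pumps (Hill-2), rapid buffering with constant
   buffering factors, and a store-operated CRAC current that relaxes with
   time constant τ toward Ī·K^4.2/(K^4.2+Ca_ER^4.2).  The ER leak and the
   resting membrane influx are derived from the configured resting point
   (0.1 μM cytosolic, 400 μM ER), so the unstimulated cell is an exact
   steady state.

Coupling is one-way from the network: pVEGFR2 → PLCγ, IP3 → calcium,
calcium → CIB1 gate.  The full system (792 network species + 13 closed-form
states) is integrated with LSODA and an analytic Jacobian for the network
block (defaults rtol 1e-7, atol 1e-9; tightening both by half changes
reported observables by far less than 0.1%, and both are overridable).
Every protocol starts from a ligand-free pre-equilibrated resting state,
and fraction-total observables are normalized to the t = 0 totals.

## Compartments and trafficking

The endosomal location is a property of the whole complex.  Complexes
containing a VEGF-crosslinked VEGFR2 homodimer internalize; TSP1-engaged
CD47/VEGFR2 units also internalize without VEGF (TSP1 application alone
destabilizes the receptor).  Endosomal complexes recycle slowly
(1.24×10⁻³ s⁻¹) unless they contain NRP1 (0.756 s⁻¹) — the two fitted
recycling rates — or a TSP1-bound CD47 (fast, like NRP1: TSP1/CD47/VEGFR2
units either recycle rapidly or degrade).  All endosomal complexes degrade
at a base rate of 1.43×10⁻³ s⁻¹.  The two TSP1 mechanisms are surcharge
rates on complexes that contain TSP1-bound CD47: degradation scaled by
`fold_deg` and receptor dephosphorylation scaled by `fold_dp`.  Because the
surcharges are written as `k·(fold−1)` extra rules on positively matched
patterns, no negative application conditions are needed and `fold = 1`
reduces exactly to the control model.

The fast recycling of TSP1-engaged complexes is the structural choice that
makes the degradation fold-change act far from saturation: the per-visit
degradation probability is fold·k_deg/(fold·k_deg + k_rec,fast), which is
nearly linear in the fold up to ~100×, so ERK survives small folds and
collapses near the threshold, instead of every fold ≥ 2 killing half the
receptors per pass.

## Why the receptor pool sizes matter

VEGFR2 (6000/cell) is slightly below CD47 (7000/cell = 5/μm² at the
derived 1400 μm² surface), so nearly every receptor can carry a CD47 and
TSP1 coverage of the phosphorylatable pool is nearly complete at 2 nM; the
uncovered remainder sets the residual signaling floor that the
dephosphorylation fold cannot touch, and its size relative to the ERK
ignition threshold is what places the very large (~80–90×) dephosphorylation
thresholds.  NRP1 (1100/cell) is stoichiometrically limiting: the
NRP1-containing complexes recycle fast and form the ~15–20% receptor pool
that survives 180 min of VEGF, while in NRP1-null cells essentially all
receptors are degraded.  VEGFR1 (300/cell) acts as a minor decoy.

## Thresholds and criteria

Scan metrics (max pR2, pR2 at 10 min, max calcium rise, max pERK, end-point
values) are computed from fresh simulations per grid point.  "Inhibited"
means a metric below 5% of its no-TSP1 control; "recovered" means above
50% of control.  Both are package definitions (configurable in
`ThresholdCriterion`); reported threshold locations depend on them, which
is why acceptance comparisons use a ±25% relative band.  Crossings are
bracketed on a 25-point grid and refined by bisection on fresh simulations
to 2% relative resolution.

## Parameter provenance

Directly adopted values: endosomal recycling 0.756 s⁻¹ (NRP1 present)
vs 1.24×10⁻³ s⁻¹ (absent); base degradation 1.43×10⁻³ s⁻¹ (one
twenty-first of the 0.03 s⁻¹ threshold rate); CRAC amplitude
Ī = 1.74×10⁴ μM/s and Hill exponent 4.2; CD47 at 5/μm² ≡ 7000/cell; the
standard stimulation protocol (2 nM TSP1 for 10 min, then 50 ng/ml VEGF
for 40 min; simultaneous addition for the therapy studies); the VEGF
ng/ml→nM conversion uses a declared VEGF-A165 homodimer mass of 38.4 kDa.

All remaining kinetic constants were calibrated with the package's own
fitting machinery against the benchmark outcomes the model is built to
reproduce:
>80% receptor degradation in 180 min, ~60% surface internalization in
5 min, complete degradation without NRP1, a ~250 nM calcium transient,
abolition of pERK under SphK1 blockade, the ~5 pM ERK dose switch, and the
TSP1 mechanism/therapy thresholds.  The calibration is genuinely
over-determined: the dose switch, the dephosphorylation thresholds and the
therapy race couple through a single ignition margin, and the final
parameter file is a compromise on that manifold.  K_CRAC (60 μM) and
τ_CRAC (5 s) follow the literature range for store-operated currents; the
calcium pump/buffer constants are standard rapid-buffering reductions.

## Synthetic data

`synth` simulates the twelve parameterization panels (receptor decay
with/without NRP1, surface decay, pVEGFR2, pPLCγ, normalized and raw
calcium, pERK with/without SphK1 blockade, VEGF surface binding, and the
pVEGFR2/pERK dose-response curves) under any parameter set, samples them
on fixed grids in each panel's presentation, and applies additive-Gaussian
or proportional observation noise.  The packaged CSV fixtures are
synthetic stand-ins generated this way (the real targets are digitized
Western-blot/flow/fluorimetry curves with no deposited data); they share
one schema with freshly generated datasets, so the fitter cannot
distinguish them.  Passing fits against these fixtures therefore
demonstrate the pipeline's correctness and identifiability on data with
the assumed statistical structure — not agreement with actual wet-lab
measurements.

## Fitting and sensitivity

The fitter is a generalized pattern search in log10 parameter space (full
±coordinate poll, greedy expansion along the winning direction, mesh
contraction 0.5 / expansion 2.0, initial mesh 0.1× the log-range), with a
weighted least-squares objective; simulation failures contribute a large
finite penalty so the search never aborts.  Identifiable-subset recovery
is demonstrated for the CRAC closure: τ and K are recovered exactly from
noiseless cytosolic+ER traces of a strong IP3 step sampled densely during
onset.  The amplitude Ī is not part of the identifiable subset: at
physiological store levels the current only exposes the combination
Ī·K^h, so amplitude and half-activation compensate along a
plateau-preserving manifold, and driving the store below K to break the
degeneracy requires unphysiological cytosolic loads.

PRCC follows the standard rank-based partial-correlation construction:
rank-transform the uniform Monte-Carlo design (default 0.01× to 50× each
fitted value) and the outputs, partial out the other parameters by linear
regression on ranks, and correlate the residuals; significance uses the
t-approximation with n−k−1 degrees of freedom.  Constant columns raise an
explicit error rather than reporting zero.

## Numerical choices and degenerate inputs

Mass-action statistical factors follow BioNetGen deterministic semantics
(embedding counts, a ½ factor for identical reactants, division by
action-invariant rule automorphisms); trafficking rules fire once per
matching complex.  The solver clamps the pVEGFR2 drive and the rate-law
inputs at zero to tolerate the tiny negative excursions a stiff solver
explores; the module-level rate functions themselves raise on negative
inputs.  Free VEGF and TSP1 are clamped boundary species in nM set by
protocol events; ligand inside complexes is ordinary state, so ligand mass
is not conserved by construction (the solution is a reservoir).

## Problem sizes used

The default analyses use the full 792-species network.  Threshold scans
use 25-point grids with 2%-resolution bisection; therapy scans 21 points;
the PRCC ranking 60 samples over 8 parameters (the package supports
arbitrary n; the ranking is stable at this size because the leading
coefficients are far from the null band).  A full protocol simulation
takes roughly a second, a threshold measurement a minute or two.

## Known limitations

* The rule inventory is a reconstruction, and equally defensible variants
  change the enumeration: this one yields 792 species and 8233 directed
  (5006 reversible-collapsed) reactions versus the 627/4174 benchmark
  counts, mostly from the VEGF-independent trafficking of TSP1-engaged
  complexes that the mechanism thresholds require.
* The benchmark threshold numbers are criterion-sensitive; with the 5%/50%
  defaults most reproduce within ±25%, but the combined-mechanism therapy
  race (simultaneous TSP1+VEGF addition) is the tightest point of the
  calibration manifold and its ERK-recovery threshold is the least robust
  reproduced quantity.
* No NO/eNOS/sGC or CD36 arms, no explicit SIRPα, no stochastic
  simulation, no spatial effects, and no mechanistic DAG/IP3 chemistry
  beyond a pPLCγ-proportional source.
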