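# Methods

## The model

`pdacmet` implements a deterministic kinetic model of central carbon
metabolism in a pancreatic cancer cell, coupled to a population-growth law.
The reference network (packaged as `src/pdacmet/data/network.yaml`) contains
46 dynamic metabolites in two compartments (cytosol, mitochondria) connected
by 53 enzymatic and transport reactions covering glycolysis, the oxidative and
non-oxidative pentose phosphate pathway, glutaminolysis (GLS and the
GOT1/GOT2/GPT transaminases), the TCA cycle, the malate/aspartate/citrate/
α-ketoglutarate/glutamate shuttles, lumped oxidative phosphorylation, the
adenylate system (adenylate kinase, ATP demand) and glutathione redox
recycling.  Each metabolite obeys one mass-balance ODE; together with the
cell-number equation the integrated system has 47 states.

Species fall into three classes:

* **dynamic metabolites** (46) — one ODE each, initialized from the packaged
  validated initial conditions;
* **fixed species** — held constant during integration: mitochondrial ATP and
  ADP (following the source-model convention for the adenine nucleotide
  translocase being lumped away), inorganic phosphate, ammonium and CO2;
* **boundary species** — extracellular glucose, glutamine, lactate, glutamate
  and alanine, imposed by the experimental protocol (media schedule), not by
  mass balance.

Rate laws use standard mechanisms: irreversible and reversible
Michaelis–Menten (uni-uni and random bi-bi with independent forward/reverse
maximal velocities), Haldane-style reversible forms with an explicit
equilibrium constant, Hill kinetics for the allosteric steps (PFK, GLS,
glutathione reductase), facilitated-carrier and antiport forms for the
transporters, and mass action for adenylate kinase.  Denominator "binding"
terms (dead-end complex sites) and multiplicative inhibitor/activator factors
carry the known regulation (e.g. G6P product inhibition of hexokinase,
AMP activation and citrate inhibition of PFK, NADH/acetyl-CoA inhibition of
PDH, respiratory control of oxidative phosphorylation).  All kinetic
constants live in the configuration file; nothing is hard-coded.

Exactly 18 reactions carry an independent reverse maximal velocity, giving
53 + 18 = 71 velocity parameters; the full inventory of velocities plus
kinetic constants is 372 parameters.  GLUT1, HK and PFK are flagged
AKT-modulated: their effective maximal velocity is
`Vmax (0.2 + 0.8 * akt_level)`, i.e. 20% basal activity plus an
AKT-proportional share.

## Growth law

Relative cell number `C_N` (inoculum = 1) obeys a logistic equation with a
death term,

    dC_N/dt = lambda (1 - C_N/K_CC) C_N - alpha_d C_N,

with the specific growth rate a sum of Monod terms on intracellular ATP,
glucose and glutamine:

    lambda = alpha_atp ATP/(k_ap+ATP) + alpha_glc Glc/(k_gc+Glc)
           + alpha_gln Gln/(k_gn+Gln).

The coupling is one-way (metabolites drive growth; cell number does not feed
back onto the per-cell metabolite balances, i.e. concentrations are per-cell
quantities under non-depleting media).  The seven parameters exposed to the
growth-fitting stage are the four rates (1/min) and three half-saturation
constants (mM); the carrying capacity `K_CC` is a configuration constant
(default 40 relative units, which keeps the five-day control curve in the
near-exponential regime).  Packaged defaults put most of the growth signal on
the ATP channel (`alpha_atp = 4.7e-4`/min, `k_ap = 0.5` mM — saturated at
healthy ATP, responsive once ATP collapses), a strong glutamine channel
(`alpha_gln = 2.2e-4`/min) and a deliberately small direct glucose channel
(`alpha_glc = 1e-6`/min), consistent with the glutamine-addicted phenotype
the model describes.

## Calibration of the reference configuration

The original model's rate equations are not available as machine-readable
files, so the network was reconstructed from the published diagram and the
cited source-model families, and then calibrated in-package:

1. A target steady-state flux distribution was designed (strongly
   "Warburg": glucose uptake 0.02 mM/min flowing almost entirely to lactate;
   glutaminolysis ~0.45 mM/min fuelling the TCA cycle through the
   GPT/GOT transaminase couple, exporting alanine and aspartate-derived
   carbon; oxidative phosphorylation supplying ~90% of ATP) and projected
   exactly onto the steady-state manifold `S v = 0`.
2. Thermodynamic displacements were assigned per reaction (classic
   near-equilibrium glycolytic/PPP enzymes at 90–95% of equilibrium;
   transaminases and carriers moderately displaced) and the equilibrium
   constants derived from the validated concentrations.
3. Every maximal velocity was then scaled so that validated initial
   condition #1 is an exact steady state of the baseline model under complete
   media (35 mM glucose, 6 mM glutamine).  The control trajectory is
   therefore flat in the metabolites and smooth in cell number, and the
   baseline flux directions are well defined.

Because mitochondrial NAD(H)/NADP(H) pools are lumped with the cytosolic ones
(the printed metabolite list carries a single pool of each), the
malate–aspartate shuttle is redox-neutral in this model.  The growth-limiting
consequences of perturbing the GOT1/GOT2 axis are instead carried by two
mechanisms with direct experimental counterparts:

* **TCA throughput → respiration.**  Lumped oxidative phosphorylation
  partially oxidizes succinate (complex II share) in addition to NADH, so
  collapse of glutamine anaplerosis starves respiration.
* **NADPH/glutathione redox clock.**  Cytosolic malic enzyme (fed by the
  GOT1–MDH1 axis) is the dominant NADPH source.  Glutathione turnover is slow
  (~0.006 mM/min against a ~2.7 mM total pool), and glutathione reductase
  depends cooperatively on NADPH, so a sustained NADPH deficit drains reduced
  glutathione over roughly a day.  Respiration requires the reduced pool
  (oxidative-damage activation term), which produces the characteristic
  *delayed* energy collapse after GOT1 knockdown: growth tracks the control
  for about a day, then ATP falls, the adenylate pool redistributes and the
  adenylate kinase net flux reverses against its baseline direction after
  day one — the dynamic signature the simulation engine's flux-reversal
  detector reports.

The knockdown-response calibration targets the qualitative behaviour pattern
the model is known for: GOT1 knockdown (α = 0.85) roughly halves day-5 cell number;
GLUT1 knockdown is nearly inert and adds nothing on top of GOT1 knockdown;
GOT2 and GLS knockdowns are strongly growth-reducing with no additional
benefit from combining GOT2 with GOT1; full oxidative-phosphorylation
knockdown is the most severe single perturbation; growth is far more
sensitive to media glutamine than to media glucose.  These are emergent
outcomes of the calibrated kinetics, not hard-wired responses.

One bookkeeping difference from the narrative the model reconstructs: with
the stoichiometry written as ATP + AMP → 2 ADP and the adenylate pool closed
except for a small PRPP-synthetase AMP source, the *steady-state* adenylate
kinase flux must be slightly forward (consuming the AMP produced by PRPP
synthesis).  The reversal under GOT1 knockdown — net ATP+AMP production from
ADP while the energy charge falls — is reproduced; only the baseline sign
convention differs.

## Initial-condition ensembles

`sampling.lhs_initial_conditions` draws Latin hypercube samples over the
packaged per-metabolite bounds (each of the `n` equal-width strata sampled
exactly once, uniformly within the stratum); metabolites present in both
compartments share one sampled value, matching the assumption that
compartment duplicates start at the same concentration.  The full-scale
design draws 100 sets and keeps 50 for estimation; both counts are configuration
defaults.  `sampling.gaussian_initial_conditions` implements the robustness
design: per-metabolite truncated normals with sd = mean/6 and ±50%
truncation (= ±3 sd, so essentially no mass is clipped).

## Identifiability

For every reversible reaction with a free reverse velocity, the Jacobian
columns of the knockdown fold-change objective with respect to ln Vf and
ln Vr are estimated by forward differences (5% steps) per initial condition;
the score is the absolute cosine similarity averaged over the ensemble
(degenerate sensitivities are reported as undefined, never as zero).  Pairs
scoring at or above the threshold (default 0.95) are reduced via
`Vr = Vf/Veq` and the analysis repeats in rounds until nothing new is
flagged.  The exact correlation statistic behind the published reduction (71 to 59
free velocities) is not documented, so the ranked table is exported for
inspection rather than a fixed pair list being assumed; on the packaged
network the two-round procedure reduces the 71 free velocities to the
mid-50s, driven by the same structural cause — near-equilibrium enzymes expose only their flux capacity,
not Vf and Vr separately.  The packaged defaults run the analysis on a small
LHS ensemble (4 sets); scores are ensemble averages and stabilize quickly,
so this reproduces the full-ensemble reduction at a fraction of the cost.

## Global sensitivity (eFAST)

`sensitivity.efast_indices` implements the resampled extended Fourier
Amplitude Sensitivity Test: each parameter in turn is driven at the maximal
admissible frequency `(N-1)/(2M)` (interference factor `M = 4`) while the
complementary parameters use distinct low frequencies from the top of the
allowed complementary band (descending assignment — mostly coprime pairs
cover the joint space far better than 1, 2, ...).  First-order indices come
from the harmonics of the driving frequency, total indices from the
complement of the low-frequency band; random phase resamples are averaged
and a dummy parameter is injected as an estimator control.  Velocities are
sampled log-uniformly over [value/100, value·100].  The estimator reproduces
the closed-form Ishigami first-order indices to well within 0.05 at
257 samples per curve.  In the pipeline this stage is reporting-only — it
does not prune parameters.

## Estimation

Stage one minimizes the WSSR between observed and predicted panel
fold-changes with a global-best particle swarm (default 50 particles,
inertia 0.7, cognitive = social = 1.5), positions in log10 space over
[v/100, v·100]; evaluation failures are penalized, not fatal; the full-scale
design of 2 runs × 2500 iterations per initial condition is the default,
scaled down in the packaged pipeline configuration.  Stage two fits the
seven growth parameters with restarted trust-region least squares, restarts
log-uniform over a seven-decade box.  Because the coupling is one-way, the
metabolite trajectories are integrated once per dataset and each
growth-parameter trial is evaluated with the exact solution of the
time-varying logistic-with-death equation (the substitution u = 1/C makes it
linear), which makes hundreds of restarts cheap and is exact up to
trapezoidal quadrature of λ(t) on the stored grid.

WSSR weights default to 1, or 1/σ² when per-observation uncertainties are
supplied.

## Synthetic studies

`synth.make_ground_truth` multiplies every free velocity by an independent
log-normal factor (log-sd = perturbation scale, default 0.3) and draws growth
parameters log-uniformly within a factor-2 box around the packaged values.
`synth.simulate_training_dataset` then emits the three datasets of the
calibration design — knockdown fold-changes at 24 h, daily growth curves over
5 days under complete media (control + knockdown), and a validation growth
dataset with glucose/glutamine withdrawal after 24 h — with multiplicative
log-normal noise at a configurable coefficient of variation (default 0.1;
0 gives the exact model predictions).  The generator emulates targeted
metabolomic fold-change panels and cell-count time courses; it does not
emulate peak-level mass-spectrometry data, batch effects, or measurement
correlations, so passing recovery tests demonstrate algorithmic correctness
on the model's own data-generating process, not robustness to real-data
artifacts.  An 8-metabolite synthetic miniature network with the same
interface is provided for fast tests.

## Numerical choices

* Stiff integration with SciPy's BDF and a conservative Jacobian sparsity
  pattern derived from the stoichiometry and rate-law roles; default
  tolerances rtol 1e-8 / atol 1e-10 for simulation, relaxed to rtol 1e-6 in
  the inner loops of fitting, identifiability and screening (atol 1e-11
  where protocols drive nutrients to zero).  The solver restarts at every
  media-switch and knockdown-onset breakpoint.
* Concentrations are clipped at zero inside rate-law evaluation; an
  integration error is raised if any state falls below −1e-9 mM.
* Knockdown onset defaults to t = 0 (pre-transduced cultures); the
  fold-change observation time defaults to 24 h.
* Flux-reversal detection ignores fluxes below a dead-band (default
  1e-9 mM/min) to suppress sign chatter around zero.
* Zero fluxes at the baseline state inherit their declared direction from
  the configuration (relevant for GLUD1, which is structurally at
  equilibrium in every steady state of this stoichiometry: its mitochondrial
  glutamate/aspartate neighbourhood forces zero net flux, matching the
  transaminase-dominated phenotype; it is calibrated to a standing capacity
  of 0.25 mM/min so it can carry flux away from steady state).

## Problem sizes used by the packaged defaults

The packaged pipeline defaults and the acceptance script scale the
full-scale design down so a complete run finishes quickly on one CPU: 4 LHS initial
conditions for identifiability (vs 100), 20-particle × 30-iteration swarms
(vs 50 × 2500), 10 growth restarts (vs 100), 65-sample eFAST curves.  All
full-scale counts remain available as configuration options.

## Known limitations

* The network is a reconstruction: individual kinetic constants are curated
  around the validated concentrations, not fitted to the original
  measurements, so quantitative flux values are model-specific; the
  conformance counts (46/53/71/372) and the qualitative knockdown/nutrient
  behaviour pattern are the reproduced quantities.
* Single NAD(H)/NADP(H) pools span both compartments; redox shuttling is
  therefore represented through the succinate and glutathione couplings
  described above rather than compartment-resolved cofactors.
* No autophagy, macropinocytosis, amino-acid or nucleotide biosynthesis
  branches; media are non-depleting; one homogeneous cell population.
* Growth feeds on ATP, glucose and glutamine only; redox stress affects
  growth through respiration, not via an explicit damage/death term.
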