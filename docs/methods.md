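# Methods

This note records the modelling assumptions, numerical choices and
deliberate simplifications behind `pbtkit`, at the level of detail a
user needs to judge what results do and do not mean.

## Whole-body model structure

The species model is a perfusion-limited (well-stirred) whole-body
network.  Fifteen organs (lung, liver, kidney, muscle, skin, adipose,
brain, heart, gonads, bone, spleen, stomach wall, small- and
large-intestinal walls, and a "rest" compartment absorbing the remaining
volume) exchange drug with three blood pools.  For organ *o* with blood
flow Q_o = specific blood flow × volume,

    dA_o/dt = Q_o (C_art − C_out,o) − elim_o,
    C_out,o = (A_o / V_o) / (K_p,o / BP),

i.e. the venous outflow leaves in equilibrium with the whole tissue.
The lung sits in series between the venous and arterial pools and
carries the cardiac output, defined as the sum of all arterial organ
inflows.  Spleen, stomach wall and the intestinal walls drain into a
portal node that feeds the liver together with the hepatic artery, so
orally absorbed drug undergoes first-pass extraction.  State variables
are amounts (µmol); three sink states (metabolized, urine, faeces) close
the mass balance identically.

Elimination drivers:

* hepatic metabolism  = CL_hep,spec · V_liver · f_u · C_liver-outflow-plasma,
* glomerular filtration = gfr_fraction · GFR_spec · V_kidney · f_u · C_arterial-plasma,
* tubular secretion  = CL_tub,spec · V_kidney · f_u · C_kidney-outflow-plasma.

These make liver volume, kidney volume, kidney perfusion and the
specific GFR functionally active parameters, which is the point of the
sensitivity analysis.

## Gastrointestinal transit and absorption

The lumen is a chain of eight segments in fixed anatomical order.  The
stomach empties first-order with the gastric emptying time; the
small-intestinal and large-intestinal transit times are split across
their segments in proportion to segment length.  Each segment also
stores its own transit rate, and the effective outflow rate used in the
equations is

    k_s = transit_rate_s · (Σ_{s'∈region} 1/transit_rate_{s'}) / T_region,

which equals 1/residence-time at build and responds to a perturbation of
either the per-segment rate or the regional time — both are listed as
independent parameters.  For the single-segment stomach "region" the
per-segment rate cancels exactly, leaving the gastric emptying time as
the only active stomach-transit parameter.

Absorption occurs in every segment except the stomach:

    flux_s = P_eff · SA_s · fn(pH_s) · min(A_s / V_s, S),

with SA_s = 2π r̄ L · SEF (surface-enhancement factor), luminal fluid
volume V_s = π r̄² L · fill_fraction (the "fractional steady-state fill
level" is interpreted as scaling the fluid volume), fn the neutral
fraction at the segment pH, and S the aqueous solubility.  The min()
term is the saturation mechanism: when the dissolved concentration is
capped, reducing the dose barely changes the absorbed flux, the
dose-normalization denominator becomes small, and gut parameters can
reach sensitivities above 1.  Absorbed drug enters the portal node;
colon outflow goes to the faeces sink.

## Partition coefficients

A compartment's affinity is `a = f_water/fn(pH) + 10^logP·f_lipid + B`.
Ionized drug is confined to the aqueous phase, so a small neutral
fraction inflates the apparent aqueous affinity.  The plasma binding
term B_p is back-calibrated from the measured f_u
(`f_u = (f_w/fn)/a_plasma`) and clamped at zero when a lipophilic,
weakly-bound compound would push the calibration negative; tissue
binding scales with the protein content relative to plasma.  Cellular,
interstitial and red-blood-cell partition coefficients are affinity
ratios against plasma; K_p,total is the vascular/interstitial/cellular
volume-weighted combination and BP = (1−HCT) + HCT·K_ery.  This is a
deliberately simple scheme in the spirit of the standard
composition-based models: it makes compositions, pH values, haematocrit
and f_u functionally active without attempting to reproduce any specific
published calibration.

## Observation sites

* `venous_plasma`: central venous pool, C_ven/BP.  At t = 0 of an
  intravenous bolus this sample is the bolus instant D/V_ven.
* `peripheral_venous_plasma`: flow-weighted mean of organ outflow plasma
  concentrations using each organ's peripheral blood-flow weight
  (muscle 0.6, skin 0.4 in the templates).
* `organ_intracellular`: (K_cell/K_p) × total tissue concentration.

## Numerics

Intravenous models, and oral models whose dose can never reach the
solubility cap (checked with the conservative bound
max_s dose/V_s ≤ S), are linear; they are propagated exactly on the
uniform output grid with a matrix exponential (`expm(M·Δt)` applied
iteratively), which is deterministic to the bit and conserves mass to
machine precision.  Because the Padé solve inside `expm` introduces
O(1e−18) fill-in into structurally unreachable states, lumen and faeces
states are explicitly zeroed for intravenous runs.  Saturable oral
models use LSODA with rel_tol 1e−8 / abs_tol 1e−10 and dense output.
Default grid: 240 samples over 24 h (i.v.) or 48 h (oral);
an i.v. bolus is an initial condition in the venous pool.  RMSD for the
sensitivity ratio is computed on the linear concentration scale over
this grid; the ratio is insensitive to the grid because numerator and
denominator share it.

One-at-a-time perturbations multiply a single leaf by 0.95 and rebuild
every derived quantity from scratch; dependent parameters are *not*
renormalized (perturbing muscle volume does not rescale other organs).
Parameters with baseline 0 are skipped with a warning, since a
multiplicative perturbation cannot move them.  The Cmax-based
alternative metric mirrors the RMSD ratio:
|Cmax(c_i)−Cmax(c0)| / |Cmax(c_dose)−Cmax(c0)|.

## Species templates and scaling

The seven packaged templates (mouse 0.02 kg … human 73 kg) are
literature-plausible approximations assembled from generic mammalian
organ-fraction, perfusion and composition tables with per-species
adjustments; they are scaffolds for method work, not curated reference
physiologies.  The mouse default of 0.02 kg reflects the lower end of
the intended body-weight span; a 0.23 kg "mouse" (a weight sometimes
quoted for grouped laboratory rodents) is reachable via
`allometric_scale(mouse, 0.23)` — the two conventions are inconsistent
in parts of the literature, so the weight is configurable rather than
hard-coded.

Allometric scaling multiplies organ and blood volumes by the body-weight
ratio r (exponent 1.0) and renormalizes so volumes sum exactly to the
target weight at density 1 kg/L; the correction is skipped below 1e−12
so re-scaling to the same weight is an exact identity.  The gut lumen
must satisfy two aggregate power laws simultaneously — total volume
∝ r^1.06, total surface ∝ r^0.76 — which is achieved jointly by scaling
lengths with r^(2·0.76−1.06) = r^0.46 and radii with
r^(1.06−0.76) = r^0.30.  Intensive parameters (pH, fractions,
compositions, specific rates, haematocrit, transit times) are untouched.
Composite quantities such as the peripheral-blood weighting are stored
explicitly rather than derived, because allometric rules for them are
not well defined.

## Synthetic data

`generate_species` applies mean-preserving lognormal jitter
(multiplier exp(σZ − σ²/2), σ² = ln(1+CV²), default CV 0.2) to volumes,
flows, lumen lengths and transit times — not to pH values or fractions —
then renormalizes the volume budget.  `generate_compound` draws from the
three clearance archetypes (renal-only, hepatic-only, mixed
hepatic+tubular) inside the small-molecule property window
MW 151–361 g/mol, logP −0.02…1.25.  `generate_observations` multiplies
model predictions by lognormal noise (default CV 0.15).

The packaged reference ensemble comprises eight (compound, route)
protocols on the rabbit template — acyclovir-like (i.v. 10 and
p.o. 25 mg/kg), caffeine-like (i.v. 5), inulin-like (i.v. 50),
ofloxacin-like (i.v. 10), paracetamol-like (p.o. 15), theophylline-like
(i.v. 5 and p.o. 10) — extrapolated to six further species (56 models).
Doses are realistic orders of magnitude but otherwise conventional
defaults.  The compounds are archetype approximations, not fitted
models: the acyclovir-like permeability (1e−6 cm/min against the
SEF-enhanced surface) was chosen so that oral bioavailability in the
rabbit model matches the literature picture for the real drug
(F ≈ 0.27 at 25 mg/kg, falling to 0.18 at 50 mg/kg through solubility-
limited absorption); the ofloxacin-like compound is treated as neutral
because the real molecule is a net-neutral zwitterion near physiological
pH (modelling it as a monoprotic acid with pKa ≈ 6 grossly exaggerates
pH sensitivity); the inulin-like tracer is a freely filtered,
non-metabolized *small molecule* — the pore-limited distribution of the
real 6 kDa fructan is out of scope, so its simulated intracellular
exposure (and the sensitivity of tox-organ water fractions under it) is
an artefact of this stand-in.

What passing tests on these synthetic conditions show: the metric's
structural identities, conservation laws, scaling laws and the
qualitative route/saturation structure of the sensitivity ranking.  What
they do not show: quantitative agreement with any specific validated
species or compound model, which would require curated physiology and
fitted compound parameters.

## Known limitations

* The ×0.95 one-sided perturbation makes any parameter with profile
  elasticity near −1 score up to |1/0.95−1|/0.05 ≈ 1.053 regardless of
  route.  In intravenous models two such families exist here: the venous
  blood volume (whose t = 0 bolus sample dominates the RMSD) and, for
  the inulin-like stand-in only, the water fraction of an observed tox
  organ.  Their scores fall in 1.01–1.04; genuinely super-dose
  sensitivities (here up to ≈ 2.3) arise only in oral models through
  absorption saturation.
* Permeability-limited organ kinetics, lymph flow, enterohepatic
  recirculation, transporters/enzymes, metabolite tracking and a
  two-pore large-molecule model are out of scope.
* The checklist's template-choice step (food-spectrum similarity) is
  advisory text; it is not computed.
* The factor-of-2 validation uses the geometric-mean fold error with the
  threshold as a parameter (default 2), since an acceptable deviation
  depends on the uncertainty and variability of the measurements.
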