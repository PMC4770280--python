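# Methods

## Model structure and assumptions

`mscpbk` treats the body as eight well-mixed compartments — arterial blood,
venous blood, lung, liver, spleen, kidney, heart and a lumped rest-of-body
— linked by the systemic circulation. Cell transport to organs is assumed
flow-limited and fast relative to cellular interactions with the vessel
wall, so the kinetics are governed by two processes: convection by blood
flow, and first-order exchange between each organ's vascular space and a
retained extravascular pool.

Topology. The lung is in series between the venous and arterial pools and
receives the entire cardiac output — this is what produces the pulmonary
first-pass entrapment characteristic of large (~20 µm) cells. All other
organs are perfused in parallel from the arterial pool. The splenic venous
outflow drains into the liver (the splanchnic/portal route), so total
hepatic outflow carries hepatic-artery plus splenic flow; this link is what
makes the intra-hepatic arterial route comparison anatomically meaningful.
The rest-of-body compartment closes both the mass and the flow balance as
the residual.

Kinetics. Venous outflow from an organ leaves at concentration
`C_V/P` with `P` a unitless, organ-specific partition coefficient — an
empirical description of how strongly the organ's microvasculature holds
cells relative to outflowing blood. Arrest, release and depletion are
first-order with rate constants in h⁻¹. Depletion in organs acts on the
*retained* pool only; the circulating arterial and venous pools carry their
own depletion rate constant (applied to both pools). All depletion fluxes
drain into a single cumulative sink with no excretion-route split, so the
dose is conserved exactly: live + depleted = administered, and survival
fraction ≡ 1 − depleted/dose. Cells act independently (no aggregation, no
flow modification, no intercellular feedback), making the system linear and
time-invariant between dose events; proliferation, differentiation and
tissue integration are excluded as much slower than the 24–72 h horizon.

Dosing. Both routes are instantaneous boluses (state jumps): intravenous
into the venous pool, intra-hepatic arterial directly into the liver
vascular space. A bolus is adequate because an injection lasts seconds
against a first sampling time of 5 min; modelling the arterial route as a
bolus into the target bed (rather than a modified arterial flow split) is
the simplest construction that reproduces the lung bypass.

## Parameters

Species physiology (YAML files under `src/mscpbk/data/`, units kg, L, L/h;
tissue density 1 kg/L): body weight, organ total and vascular volumes,
regional flows, arterial/venous pool volumes and cardiac output for mouse
(0.025 kg), rat (0.25 kg) and human (70 kg). Values are transcribed from
the standard reference compilations (Brown et al. 1997; Davies & Morris
1993; ICRP 89) with per-value provenance comments; vascular-volume
fractions (lung 0.50, liver 0.31, spleen 0.17, kidney 0.24, heart 0.26,
rest 0.02) come from the same rodent blood-content tables and are plain
config values a user can edit. Validation enforces positive entries,
vascular < total volume, the 1% circulatory flow balance, and total volume
≤ body weight. `scale_physiology` rescales volumes proportionally to body
weight and flows with the standard allometric exponent 0.75.

Cell kinetics (`msc_reference_params.yaml`, loadable as `"reference"`): per
organ a partition coefficient (0.1–10⁴ plausible range; reference values
span 3.1 for heart to 1633 for spleen) and arrest/release/depletion rate
constants (10⁻⁴–10² h⁻¹; reference values 0.002–5.434 h⁻¹), plus the blood
depletion rate constant (0.636 h⁻¹). The lung's arrest rate (5.434 h⁻¹) is
the largest, encoding dominant pulmonary entrapment; blood's depletion rate
is the largest clearance term, encoding the blood pool as the major
elimination site.

## Numerical choices

- Simulation default is LSODA with rtol 1e−8, atol 1e−6, analytic Jacobian
  (the system's constant rate matrix); rates spanning 0.002–5.434 h⁻¹ with
  partition coefficients up to 1633 give moderate stiffness. Because the
  system is linear, an exact matrix-exponential propagator (`solver="expm"`)
  is available and is used inside calibration and sensitivity loops, where
  thousands of smooth, noise-free evaluations matter; a fixed-step RK4
  integrator exists as an independent cross-check. The test suite verifies
  LSODA, expm and RK4 against each other and against the conservation and
  linearity identities.
- Calibration minimises unweighted least squares on log10 concentration
  (cells/kg, clipped below at 1 cell/kg) with bounded trust-region least
  squares in log10 parameter space. The log loss reflects that observed
  concentrations span ~4 orders of magnitude across compartments; the clip
  keeps zero observations finite without breaking scale-invariance above
  1 cell/kg. Bounds default to P ∈ [0.1, 10⁴], rates ∈ [10⁻⁴, 10²] h⁻¹.
  An optional seeded multi-start (perturbing the start by up to ±0.5
  log10) emulates manual re-initialisation; with a single organ block free
  the objective is well-behaved and one start suffices. Observed "blood"
  maps to the venous pool (terminal venous sampling). With all 25
  parameters free against a 6-compartment × 6-time design the fit is not
  identifiable; recovery experiments therefore free one organ block at a
  time.
- Sensitivity uses a forward difference with a +0.1% parameter perturbation
  (RSC = (ΔC/C)/(ΔP/P)) evaluated by default at 24 h, when circulating
  levels have reached a relative steady state; a central-difference mode
  exists for verification and agrees to <1%. A zero baseline concentration
  makes the RSC undefined and raises an error rather than returning 0. The
  dose, a provably unit-RSC input of this linear system, serves as a
  harness check.
- Prediction errors use the Sheiner–Beal percentage forms relative to
  observations, with 95% t-intervals over the per-pair (absolute) relative
  errors; R² is the squared correlation of the regression of predicted on
  observed, both log10-transformed.

## The synthetic-data generator

`generate_dataset` emulates the terminal-sampling mouse experiment that the
reference parameters were estimated from: 5 × 10⁵ cells IV, groups of 5
animals sacrificed at 5 min, 15 min, 1, 3, 10 and 20 h, measuring blood,
lung, liver, spleen, kidney and heart as cells per kg of tissue.
Measurement noise is multiplicative lognormal with CV 0.25 per replicate
(mean-preserving), reflecting the right-skewed, scale-proportional error of
rare-event flow cytometry; only the replicate mean and sd are recorded, as
such studies report. The CV is a convention — published reports give only
mean ± sd figures, not replicate-level dispersion — and is exposed in
config. The generator does not emulate gating artefacts, dissociation
losses, detection limits, inter-animal physiological variability, or
day-to-day batch effects; passing recovery tests therefore demonstrates
identifiability under the stated noise model and design, not robustness to
every failure mode of real cytometry data.

`generate_disease_variant` scales one organ's partition/arrest/depletion
parameters to mimic disease states (e.g. an infarcted heart arrests more
and depletes less; a cirrhotic liver partitions and arrests more), which
exercises the masked re-calibration workflow.

## Problem sizes

Default analyses use a 97-point output grid over 0–24 h; the solver
cross-check uses RK4 at a 1e−4 h step over the same horizon; recovery
experiments use 20 replicate synthetic datasets with the 6 × 6 design
above. `scripts/acceptance.py` re-runs all of these from scratch in a few
seconds.

## Known limitations

- The vascular-volume fractions are the least constrained physiological
  inputs and several sensitivity magnitudes sit near decision boundaries:
  under the bundled mouse physiology the liver arrest rate's RSC on the
  24 h liver concentration is ≈0.45, marginally below the conventional 0.5
  high-sensitivity cut that the neighbouring liver/lung partition, arrest,
  release and depletion parameters exceed. Users with tighter organ
  blood-volume data should edit the physiology files.
- Whether blood depletion applies to both circulating pools or the venous
  pool only, and whether organ depletion should also touch the vascular
  pool, cannot be decided from organ-level data alone; the implemented
  convention (both blood pools; retained pool only) follows the model
  diagram's attachment of depletion to the retained compartments.
- Linearity is an assumption, not a finding: at much higher doses,
  aggregation and flow changes would break dose-proportionality, and the
  model deliberately carries no such mechanisms.
- The rest-of-body compartment lumps gut, muscle, skin, bone and brain;
  predictions for any specific unlisted tissue are not meaningful.
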