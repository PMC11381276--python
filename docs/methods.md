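# Methods

This note records the models, conventions and design choices behind
`preclinpk`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and where the genuinely open choices
were resolved.

## Units and data model

Time is in hours in vivo and minutes in vitro; concentrations in ng/mL
(1 ng/mL = 10⁻³ mg/L); doses in mg per kg body weight. Conversions are
explicit functions — nothing converts implicitly. A concentration–time
profile is one subject × matrix series with strictly increasing times and
its dose event; sex is kept explicit on every profile and group summaries
never pool sexes silently (pooling, where used for PBPK validation, is a
documented choice, see below).

The species registry carries, for mouse/rat/dog/monkey/human:
microsomal protein per gram liver (45, 44.8, 77.9, 45, 48.8 mg/g), liver
weight per kg body weight (87.5, 40.0, 32.0, 32.5, 25.7 g/kg) and hepatic
blood flow (90, 55.2, 30.9, 44, 20.7 mL/min/kg). The scaling factor
SF = MPPGL × liver/body-weight ratio is always derived, never stored, so
registry consistency is structural (e.g. SF_human = 48.8 × 25.7 =
1254.16 mg/kg).

## Non-compartmental analysis

* **Integration.** Default is linear-up/log-down: a segment uses the
  logarithmic trapezoid only when both concentrations are positive and
  declining, otherwise the linear rule. The log rule is exact on
  mono-exponential decline, which anchors the closed-form oracle tests.
  AUMC always uses the linear rule on t·C (the usual moment convention).
* **Terminal slope.** λz is the negative OLS slope of ln C on t. Best-fit
  mode enumerates every terminal window of ≥ 3 quantifiable points,
  excludes Tmax for extravascular profiles (includes it for iv bolus),
  maximises adjusted R², and breaks ties toward more points. All
  non-negative candidate slopes constitute a no-terminal-phase error.
* **iv-bolus C(0).** For iv bolus profiles the concentration at t = 0 is
  back-extrapolated log-linearly from the first two quantifiable points
  (falling back to the first observed concentration when the initial
  segment is not declining) and the profile is anchored at t = 0, so the
  pre-first-sample area enters AUC and AUMC. Without this anchor, CL on a
  profile first sampled at 2 min is biased high by the missed initial
  area.
* **BLQ.** Below-quantification samples before the peak count as zero;
  after the peak they are dropped from the terminal fit and from AUC
  beyond the last quantifiable point.
* **Derived parameters.** AUC₀₋∞ = AUC_last + C_last/λz;
  AUMC₀₋∞ = AUMC_last + C_last·t_last/λz + C_last/λz²; MRT = AUMC/AUC
  (absorption-inclusive for oral profiles — the oral MRT convention was
  open and the uncorrected form is reported); CL = Dose/AUC₀₋∞ and
  Vz = CL/λz, both flagged *apparent* (per-F) for oral routes.
* **Bioavailability.** F% from mean AUCs uses AUC to the common last
  quantifiable time (AUC₀₋₁₂ₕ in rat, AUC₀₋₂₄ₕ in dog) by default; the
  bundled reference F cells reproduce from those means, not from AUC₀₋∞.
  One bundled cell (rat male 25 mg/kg, 82.8%) is inconsistent with its
  own printed means (which give 41.9%) and is excluded from reproduction
  checks rather than fitted; likewise one rat female Cmax dose-ratio cell
  (printed 6.76, printed means give 6.70).
* **Tmax ties** go to the earliest time. Between-sex comparisons are
  provided as a plain Welch two-sample test report field only.

## Protein binding

Bound% = (C_total − C_free)/C_total × 100 per replicate; level means,
then an unweighted across-level average, and fup = 1 − average/100.
A buffer-side excess returns a negative bound% with a warning rather than
silently clipping. The compound card carries the resulting fup per
species (rat 0.61, human 0.27, mouse 0.507, dog 0.126).

## Microsomal stability and IVIVE

ke is the negative OLS slope of ln(% remaining) on incubation time,
replicates averaged per timepoint, the t = 0 point included (exclusion is
available as an option). The chain is

    T1/2 = 0.693/ke
    CLint = ke / C_protein × SF          [mL/min/kg], C_protein = 1 mg/mL
    CLh   = Q · fu_b · CLint / (Q + fu_b · CLint)
    ER    = CLh / Q

with fu_b, the unbound fraction in the incubation, fixed at 1 (negligible
microsomal binding for this compound) but exposed as a parameter. The
constant 0.693 is the conventional rounded ln 2 used in the reported
chain; reported-table agreement is asserted at half a unit in the third
significant figure because no single constant reproduces every printed
half-life cell under strict rounding. ke = 0 (no measurable depletion)
yields CLint = CLh = ER = 0 with a censored (infinite) half-life.
Assay controls are a pass/fail QC report (positive control ≤ 1%
remaining; inactivated-microsome control within 90–110%), not a computed
endpoint. Metabolite profiles are semi-quantitative peak-area
normalisation over detected peaks only.

## Disposition

Excretion intervals carry concentration × volume (or weight, with a
configurable homogenate dilution factor, default 1:5 g/mL for feces
homogenates) and convert to % of the administered dose
(dose/kg × body weight × n_animals for pooled cages). Cumulative curves
are non-decreasing by construction; overlapping intervals are an error;
total recovery above 100% warns. Tissue exposure uses the same trapezoid
engine over the sparse tissue schedule (0.167–8 h) with no extrapolation
— too few points for a terminal fit — and reports Kp_obs = AUC_tissue /
AUC_plasma ranked descending. Published tissue-to-plasma multiples are
carried as display annotations only, because the underlying raw tissue
concentrations are not available to recompute them.

## PBPK model

**Structure.** Fourteen perfusion-limited organs (lung in series with the
venous return; adipose, bone, brain, heart, kidney, muscle, skin, gut,
spleen, stomach, gonads, liver, rest) plus arterial and venous blood and
a gut-lumen depot. Stomach is handled as a portal-drained viscus
alongside gut and spleen; the observed high stomach exposure is not
specially fitted. For each organ,
dA_T/dt = Q_T·(C_art − C_T·BP/Kp_T); the liver receives hepatic arterial
plus portal inflow and the absorption flux; oral dosing places fa × dose
in the lumen with first-order ka into the liver inflow. Amounts are in
mg; cumulative hepatic and renal elimination are explicit states, so the
mass balance (body + eliminated + unabsorbed = dose) is checked at every
output time; the suite requires < 10⁻⁶ relative.

**Physiology.** Organ volumes, regional flows, GFR and haematocrit for
rat (0.25 kg) and a 60 kg reference human are transcribed from standard
physiological compilations and shipped as versioned YAML files; the flow
topology (lung = cardiac output = Σ arterial draws; liver inflow =
arterial + portal) is validated on load and at model construction. Total
hepatic flow equals the IVIVE registry values (55.2 / 20.7 mL/min/kg) by
construction. Tissue composition (extra/intracellular water, neutral
lipid, neutral phospholipid, acidic phospholipid) is taken from the
standard rodent composition tables and assumed conserved across species —
a documented simplification; human-specific compositions would shift Kp
values modestly but not the validation conclusions.

**Partitioning.** Rodgers–Rowland moderate-to-strong base equations
(pKa 9.0 ≥ 7): extracellular water, pH-partitioned intracellular water
(pH 7.0 cell / 7.4 plasma), electrostatic association of the cation with
acidic phospholipids, and neutral-lipid/phospholipid partitioning of the
neutral species (vegetable-oil-corrected logP for adipose). The
acidic-phospholipid affinity is back-calculated from erythrocyte
partitioning (pH 7.22) implied by the blood:plasma ratio; B:P was not
measured and defaults to 1 (exposed parameter). Plasma is treated as
aqueous with protein binding carried entirely by fup, so
Kp = Kpu × fup; a tissue of plasma-like (all-aqueous) composition then
has Kp = 1 for a neutral non-binding compound, and the lipid-insoluble
limit is the tissue water (plus the 70% aqueous-equivalent fraction of
neutral phospholipid). The resulting rat Kp set gives Vss ≈ 3.0 L/kg
(observed terminal Vd 4.9–6.8 L/kg), deterministic in its inputs.

**Clearances — the recorded reference configuration.** Hepatic
elimination is unbound-driven intrinsic clearance on the liver
compartment, CLint_scaled · fup · C_liver/(Kp_liver/BP), the well-stirred
equivalent of the IVIVE chain (rat CLint 28.9 mL/min/kg from the
microsomal depletion rate). Bottom-up clearance accounting does not close
for this compound: observed rat systemic plasma clearance is
≈ 50 mL/min/kg while well-stirred hepatic clearance predicts ≈ 13 and a
renal clearance computed as urinary amount/AUC at the excretion-study
dose adds ≈ 12–21. The excretion study nevertheless shows urine as the
dominant route of the parent compound, so the reference configuration
closes the budget middle-out: CL_R = observed pooled iv plasma clearance
− well-stirred CLh (36.9 mL/min/kg). The strictly bottom-up mode
(`renal_mode="ae_over_auc"`) is retained and, as expected, fails the
two-fold validation band at the low dose — a finding the validation
report records rather than hides. Human renal clearance scales the rat
value by the GFR ratio (1.8/5.2 mL/min/kg); human hepatic clearance uses
the human microsomal CLint (18.7 mL/min/kg) with human fup 0.27.

**Absorption.** fa defaults to 1 (solubility 3450 mg/L at the doses
studied); ka is fitted by grid search to the pooled observed oral Tmax
(≈ 0.39 h), giving ka ≈ 2.1 h⁻¹. A Papp-derived ka is deliberately not
the default: the measured Caco-2 Papp (3×10⁻⁷ cm/s) implies far slower
absorption than the observed Tmax, an in vitro/in vivo discrepancy the
Tmax fit sidesteps.

**Solver.** LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ mg, output on a 0.01 h
grid; negative states beyond tolerance and non-convergence raise.
Halving tolerances changes AUC by far less than 0.1%. Simulations are
bit-reproducible for identical configurations.

**Validation.** Predicted/observed ratios of Cmax and AUC₀₋₁₂ₕ at oral
10/25/50 mg/kg against the pooled-sex observed means (the study reports
no significant sex difference; pooling is the unweighted mean of the two
sex means, n = 3 each). Acceptance band 0.5–2.0 per ratio. Under the
reference configuration all six ratios pass (1.80, 1.87, 1.25, 1.26,
0.95, 1.12); the low dose is nearest the boundary because the in vivo
exposure rises supra-proportionally with dose while the model is linear.
The human projection simulates single oral doses of 5–150 mg over 24 h;
with linear kinetics the predicted exposures are exactly
dose-proportional.

## Synthetic data generators

Generators emulate the study design: one/two-compartment closed-form
kinetics on the study sampling schedules with lognormal multiplicative
residual error and lognormal between-subject variability;
mono-exponential microsomal depletion on the 0–120 min (or 0–30 min)
schedules; dialysis equilibria at 1/4/20 µg/mL; first-order interval
excretion on the 0–96 h schedule. Every generator is a pure function of
its configuration including the seed. Noise-free mode reproduces the
closed forms to machine precision, which is the basis of all round-trip
tests. What they do **not** emulate: assay-specific error structure
(additive LLOQ-region noise, carry-over), enterohepatic recirculation,
nonlinear (supra-proportional) absorption, and inter-occasion
variability — so parameter-recovery tests demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

## Problem sizes and numerical choices in the test suite

Recovery tests use 100–200 simulated subjects or 200–500 seeded assay
replicates; PBPK property tests run single 4–12 h simulations; the
complete suite runs in well under a minute on one CPU. Table-anchored
assertions use half a unit in the third significant figure (or the
printed precision where coarser); oracle-based assertions use the
tolerance stated with each property (1–5%). Rounding for report display
is half-even at 3 significant figures.

## Known limitations

* Perfusion-limited tissues only; no permeability-limited organs, no
  mechanistic gut (dissolution/transit), no enterohepatic recycling, no
  virtual-population variability.
* The middle-out renal clearance makes total systemic clearance match
  the observed iv value by construction; the validation therefore chiefly
  tests distribution (Cmax, shape) and first-pass handling, and the
  configuration is recorded in every validation report precisely because
  a fully bottom-up parameterisation does not reproduce the observed
  clearance.
* Tissue composition shared between rat and human Kp prediction.
* The dose-exposure nonlinearity seen in vivo (rising dose-normalised
  AUC) is outside a linear model; dog PBPK is not included.
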