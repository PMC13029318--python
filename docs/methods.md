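# Methods

## Scope and model structure

`gentapbpk` simulates intravenous gentamicin disposition in dogs as a
whole-body, perfusion-limited PBPK model reduced to seven compartments:
arterial blood, venous blood, muscle, adipose, kidney, liver, and a pooled
"rest" compartment closing the mass balance (total body volume 1.0 L/kg).
The reduction keeps exactly the degrees of freedom the analysis exercises —
muscle and adipose dominate the distribution volume, the kidney carries
elimination — and pools everything else. Organ volumes and regional flows
are stored per kg body weight (cardiac output 7.2 L/h/kg ≈ 120 mL/min/kg)
and scale linearly with weight; with per-kg dosing this makes plasma
concentrations independent of body weight, so renal function (GFR per kg) is
the only axis of inter-individual variability that reaches the concentration
scale.

State variables are compartment drug amounts (mg). Tissues follow
flow-limited mass balances `dA_t/dt = Q_t (C_art − C_t·BP/Kp_t)`; venous
blood collects tissue outflows and receives doses (bolus impulses or
zero-order infusions); arterial blood receives cardiac output from the
venous pool.

## Partitioning

Tissue:plasma partition coefficients use a composition-based formula,
`Kp = kp_scale · (f_water + K_lipid f_lipid + K_protein f_protein)` with
`K_lipid = 10^logP` (logP −1.6) and `K_protein = 0.1`. Gentamicin is treated
as fully ionized at physiological pH — the single tabulated acidic pKa
(12.55) on a polybasic aminoglycoside makes any pH-partitioning term
meaningless, and the drug's extracellular distribution supports ignoring it.
`kp_scale = 0.25` is a calibration constant chosen once so the steady-state
volume of distribution is ≈0.23 L/kg, inside the physiologically expected
0.20–0.30 L/kg band for aminoglycosides in dogs and consistent with the
validated peak-concentration range (≈4.2 µg/mL per mg/kg dosed over 5 min).
Any organ Kp can be overridden per configuration.

## Clearance and elimination

Gentamicin is eliminated by glomerular filtration of unbound drug:
`CL_renal = fu · GFR · weight` (fu 0.85, healthy GFR 3.3 mL/min/kg, so
CL ≈ 0.168 L/h/kg ≈ the 0.17 L/h/kg reference plasma clearance). The
elimination flux is `CL_renal · C_art/BP` — filtration of incoming arterial
plasma, debited from the kidney compartment. Referencing the flux to kidney
*outflow* concentration instead would depress systemic clearance by the
renal extraction factor `1/(1 + CL/(Q_k·BP))` ≈ 15%, breaking the identity
AUC = dose/CL that anchors the whole dosing analysis. The flux form requires
`CL_renal < Q_kidney·BP`, a bound gentamicin satisfies ~6-fold. An optional
unspecific (hepatic) clearance, default 0, acts identically on the liver.

On clearance units: the tabulated reference value is printed as
"0.17 ml/min/kg", which is mutually inconsistent with the tabulated observed
exposures — an AUClast of 2741.55 µmol·min/L after 4 mg/kg converts to
≈21.8 mg·h/L and implies CL ≈ 0.18 **L/h/kg**. The package reads the
reference clearance as L/h/kg throughout; the unit-consistency check in the
acceptance suite recomputes this conversion.

## Sampling convention

Reported plasma concentration is the flow-weighted venous outflow of the
non-eliminating sampled tissues (muscle, adipose, rest), divided into plasma
via Kp — the peripheral-venous convention of clinical sampling. After
distribution this equals arterial plasma exactly (so AUC∞ = dose/CL holds to
trapezoid accuracy, ≈0.15% on the default grid), while during a 5-minute
infusion it lags the arterial concentration the way a limb sample does.
Sampling the arterial or mixed-venous pool instead would either fold the
injection-site mixing spike into Cmax or depress AUC by the renal extraction
fraction.

## Numerics

The inter-dose system is linear and time-invariant. The default solver is
LSODA (rtol 1e-8, atol 1e-13 mg) restarted at every dose event; an exact
matrix-exponential propagator over the same piecewise-constant-input
segments serves as an independent cross-check (tests require agreement to
1e-6 relative). The output grid uses 0.02 h steps for the first hour after
each dose and 0.25 h elsewhere, and always contains end-of-infusion times
(where Cmax of short infusions lives) and pre-dose trough times (next dose −
1e-6 h). Mass balance — administered = in-body + eliminated — is tracked as
an explicit state and holds to <0.1% (tests) and typically ~1e-12.

Parameter identification minimizes summed squared log-concentration
residuals (Levenberg–Marquardt on log-parameters, finite-difference step
1e-4 so solver noise cannot corrupt the gradient). Concentrations below a
1e-6 µg/mL quantification floor are clamped; without the floor, the
below-assay tail dominates the log objective far from the optimum and stalls
the optimizer.

## Virtual populations

Each renal stage scales the healthy GFR by a fraction: healthy 1.0,
microalbuminuria 0.80, UPC ≥ 2 0.50, sCr ≥ 1.2 0.40, sCr ≥ 2.4 0.20,
sCr ≥ 5 0.10. These fractions are **calibration constants**: the defining
clinical staging study reports biomarker classes, not numeric GFR fractions,
so the shipped values were chosen once to reproduce the ordering and the
robust cells of the published risk grid, and are configurable. Body weight
is uniform on 8–12 kg; individual GFR is `GFR_stage · exp(η)`,
η ~ N(0, σ) with σ = sqrt(ln(1+CV²)) and CV 0.15 (the standard PopPK
exp-normal convention; the stage value is the population median and the CV
is exact). No variability model beyond the weight range is stated by the
source analysis; the lognormal-GFR choice is ours.

Population exposure uses an exact-linearity fast path: for each (stage,
regimen shape) one ODE sweep over ≤24 log-spaced GFR nodes at 1 mg/kg, then
monotone PCHIP interpolation of log-metric vs log-GFR at each individual's
GFR, scaled linearly by dose. Weight cancels (per-kg scaling) and the model
is linear in dose, so the only approximation is the GFR interpolation;
tests pin it against direct per-individual ODE solves at <0.5% relative
error. This is what makes n = 2,000 × 5 doses × 6 stages × 3 intervals a
minutes-scale computation on one CPU.

## PK/PD and risk evaluation

Exposure metrics per individual: trapezoidal AUC24 over [0, 24) h (day 1)
and over the final dosing interval's first 24 h; Cmax as the grid maximum;
troughs interpolated 1e-6 h before the next scheduled dose. PTA is the
exact population fraction (integer count over n) attaining
`Cmax/MIC ≥ 10`, `AUC24/MIC ≥ 50` or `AUC24/MIC ≥ 110`; the AUC index uses
the day-1 AUC24 (configurable to the final interval). All threshold
comparisons — PTA ≥ 90%, risk ≤ 10%, and the metric thresholds themselves —
are inclusive. Nephrotoxicity risk is assessed on the final dosing interval
(day 3 for q24h): with linear kinetics the final interval dominates day 1,
so this is the conservative reading of a first-and-third-day assessment.
The MIC panel is {0.25, 0.5, 1, 2, 4, 8} µg/mL. q36h and q48h regimens keep
3 doses, mirroring the three-administration design.

Sensitivity analysis is one-at-a-time forward perturbation (default +10%):
`S = (Δm/m)/(Δp/p)`. Note the forward difference of AUC ∝ 1/CL at +10% is
−0.909, approaching −1.0 only as the perturbation shrinks; tests assert
both values at their respective step sizes.

## Synthetic ground truth

Recovery and qualification tests run on data from a closed-form
two-compartment IV model — deliberately *not* the PBPK simulator, so the ODE
machinery is never tested against itself. Defaults (CL 0.17 L/h/kg,
V1 0.20 L/kg ≈ extracellular water, V2 0.03 L/kg, Q 0.5 L/h/kg) are
moment-matched to the reference-dog disposition; sampling times
{0.083…24} h mirror the dense-early/sparse-late designs of the source
studies; residual noise is multiplicative lognormal (default CV 0.2,
matching reported inter-animal scatter) with cross-subject SDs attached for
weighted-residual work. What a green test establishes: the fitting and
statistics machinery recovers known truth under realistic noise (clearance
bias ≈ −3% to +1%, RMSE ≈ 4% at CV 0.2). What it does not: fidelity to real
digitized dog data, which is not redistributable — the printed
predicted/observed AUClast pairs are the only real-data anchor, and they are
used for the fold-error, two-fold and unit-consistency checks. The ≈1%
clearance bias that survives at zero noise is the structural two-compartment
vs PBPK gap, not an estimator defect.

## Known limitations

* **No deep-tissue pool.** Real gentamicin accumulates in the renal cortex,
  producing a days-long terminal phase. The seven-compartment reduction has
  no such pool, so healthy-kidney troughs at 24 h are ~1e-7 µg/mL and the
  published nonzero trough risks at high doses in *normal-GFR* dogs (and the
  graded trough-risk structure of the mildly impaired stages) are not
  reproduced. The benchmark outcomes deliberately rest on cells robust to
  this: extreme 0%/100% risk cells and dose picks with wide margins.
* Stage GFR fractions and the healthy GFR are calibration constants, not
  measured values.
* IV administration only; no saturable cortical uptake, no drug–drug
  interactions, no interspecies scaling.
* The two-compartment generator emulates disposition shape and noise, not
  study-level covariates (weights, breeds) of the historical datasets.
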