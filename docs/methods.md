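# Methods

## Pharmacokinetic model

Piperacillin disposition is modelled as a single well-stirred compartment
with first-order elimination — adequate because the drug has a small
volume of distribution, low protein binding and predominantly renal
elimination, and because all levels are drawn under continuous infusion at
or near steady state. Concentrations are total drug; no protein-binding
correction is applied.

For a zero-order infusion at rate R into volume V with clearance CL
(k = CL/V):

- during the infusion: `C(t) = (R/CL)(1 − e^{−kt})`
- after it ends: mono-exponential decay of the end-of-infusion value.

The full time course superposes the finite loading infusion (default
2000 mg over 0.25 h) and the maintenance infusion. Both start at t = 0;
starting the maintenance infusion 15 min later instead changes the 24 h
concentration by well under the assay noise and nothing at steady state.
The plateau `c_ss = daily_dose/(24·CL)` is independent of V, so V (default
0.25 L/kg × body weight, a typical piperacillin value) only affects
transient timing. The closed form is verified against adaptive
Runge–Kutta integration of the ODE in the test suite and the acceptance
script; agreement is at integrator precision, far inside the 0.5%
tolerance asserted.

Dose changes relax the concentration as
`C(t+Δ) = c_ss,new + (C(t) − c_ss,new)e^{−kΔ}` (linear PK). With typical
k ≈ 0.3–0.4 h⁻¹ a 24 h sampling interval is ≥ 7 half-lives, so samples are
effectively at the new plateau; the slowest realistic patients
(k ≈ 0.08 h⁻¹) are the reason the loading dose exists, and the transient
solution shows the 24 h level still lands within ~2 mg/L of plateau.

## Renal function and clearance prediction

CrCL uses Cockcroft–Gault with actual body weight
(`(140−age)·weight/(72·scr)`, ×0.85 for women); no obesity adjustment by
default. Predicted piperacillin clearance is a transparent linear model

```
CL_pred = CL_nonrenal + slope·CrCL (+ sieving × effluent flow under CRRT)
```

with defaults CL_nonrenal = 3.0 L/h, slope = 0.113 L/h per mL/min,
sieving = 0.8, effluent 2.0 L/h. Clearance-prediction dosing calculators
used in practice do not publish their internals; this linear reconstruction
was calibrated once so that the typical ICU CrCL of 47 mL/min maps to
≈ 8.3 L/h, the clearance such software predicts at that renal function, and
every coefficient is exposed in configuration. Whether the true scaling is
linear, piecewise or population-PK-based is unknown; linearity is the
assumption made here, flagged deliberately. Intermittent haemodialysis is
modelled interdialytically only (continuous infusion between sessions);
intradialytic removal would need session parameters that are not part of
the model. CRRT patients retain their residual-renal term.

## Dosing policy

Empiric daily dose = `48 mg/L × CL_pred × 24 h`, rounded to 500 mg
(practical vial sizes; ties round up) and clipped to 2000–16,000 mg/day.
48 mg/L is the centre of the 32–64 mg/L window (2–4× the P. aeruginosa MIC
breakpoint of 16 mg/L); the exact set-point used clinically within that
window is not published, so mid-window is the configurable default. TDM
adjustment is proportional (`dose × 48/c_obs`), triggered only outside the
window, with re-sampling 24 h after each change and at most 6 levels per
patient. The guideline standard-dose comparator
(CrCL ≥ 40: 12,000; 20–40: 8000; < 20 or iHD: 4000; CRRT: 8000 mg/day;
bands half-open [low, high)) is a reconstruction anchored to the typical
predicted standard median of 12,000 mg/day at CrCL ≈ 47 mL/min and is
user-overridable.

## Exposure bands and statistics

Bands partition (0, ∞) at 16/32/64/96 mg/L. Published band labels overlap
("16–32", "32–64"), so a convention is required: the therapeutic band is
closed, `[32, 64]`, favouring the inclusive phrasing "32–64 mg/L", and the
neighbours are half-open accordingly — a reading of exactly 64 counts as
therapeutic. Under continuous infusion, 100% fT>k×MIC reduces to
plateau > k×MIC, so cohort attainment above a band edge is exact count
arithmetic.

Prediction error uses the ratio `r = pred/obs`: bias = median(r) − 1,
precision = median(|r|) (with positive data this equals the median ratio;
medians because the ratios are not normally distributed). Band-by-outcome
effects are unadjusted 2×2 odds ratios with the Woolf interval
`exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))` and a two-sided Wald p-value on
the log OR; zero cells raise an error directing the user to the optional
Haldane–Anscombe +0.5 correction rather than correcting silently. No
multiplicity correction is applied across bands. Multivariate (severity- or
renal-adjusted) outcome models are out of scope; the assembled per-patient
table is exported so any statistics package can fit them.

## Synthetic cohort

The generator emulates the marginal structure of an elderly septic ICU
population: age truncated-normal (median 75, IQR 15 y), weight log-normal
(78 kg, IQR 18), height normal (170 cm), 64% male, 10% CRRT / 8% iHD, 30%
septic shock, SOFA-like severity log-normal (median 6, IQR 6). Serum
creatinine is log-normal — median 1.15 mg/dL (σ = 0.60) off RRT, 2.5 mg/dL
(σ = 0.4) on RRT — with correlation 0.5 between age and log-creatinine.
The published marginals (creatinine 1.18, CrCL 47 mL/min) are not jointly
reachable under Cockcroft–Gault with independent marginals, so the
calibration favours the CrCL median (the covariate that drives dosing):
the frozen defaults give cohort medians age 75 (IQR 15), weight 78 (18),
CrCL ≈ 48.6 (54) at n = 20,000. Distribution families are a modelling
choice; only medians/IQRs of the real population are known.

True clearance is `CL_pred × e^η`, η ~ N(0, ω²) with ω = 0.4, chosen to
produce the wide clearance spread seen in critically ill cohorts (no
numeric dispersion is published). Assay noise is multiplicative log-normal
with σ = 0.10 (median-unbiased, matching HPLC-level imprecision).
Severity and renal function are sampled independently (the real joint
distribution is unknown; a correlation hook would be the natural
extension). Hospital mortality is a logistic process on severity plus
exposure-band log-odds offsets (+0.95 for 64–96 mg/L, +1.65 for >96 mg/L
against intercept −1.1, slope 0.15/SOFA point). These coefficients are
illustrative — they exist so band-by-outcome summaries have a gradient to
detect — and are not estimates of any real-world association.

What passing tests therefore show: the pipeline's arithmetic, the
direction of its effects (clearance-guided dosing beats flat dosing; TDM
improves attainment and removes >96 mg/L levels; calibrated prediction is
median-unbiased), and exact recovery under zero noise. What they do not
show: real-data effect sizes. Real cohorts have time-varying clearance,
model misspecification between predicted and true clearance (here the
generator uses the same linear model, so prediction error is purely the
log-normal variability), informative sampling times, and confounded
mortality — none of which the generator emulates.

## Numerical choices and problem sizes

- Dose rounding: `floor(x/inc + 0.5)·inc` — deterministic, ties up.
- The closed-form/ODE comparison uses 100 random draws of
  (CL ∈ [1, 20] L/h, V ∈ [10, 50] L, dose ∈ [2, 16] g/day) at 0.5%
  tolerance; the integrator is split at the loading-infusion end so the
  rate discontinuity never crosses a step.
- Marginal-calibration checks use n = 2000 patients; the noiseless
  recovery check n = 300; the paired TDM-vs-empiric comparison n = 500.
  These sizes put Monte-Carlo error well below the asserted tolerances
  while keeping the suite fast.
- Determinism: all sampling derives from `numpy.random.SeedSequence`
  spawned from a single integer seed (demographics, assay noise and
  outcomes on separate streams), so repeated runs are byte-identical.
- Degenerate inputs (non-positive concentrations or clearances, inverted
  time grids, overlapping dose-table bands, zero contingency cells) raise
  `ValueError` with the offending quantity named; CSV errors cite the row.

## Known limitations

- One compartment, total drug, no tissue/site-of-infection kinetics, no
  tazobactam, no nonlinear or time-varying clearance.
- The linear clearance-prediction model is a documented reconstruction,
  not the proprietary calculator it stands in for.
- Cockcroft–Gault only; no CKD-EPI/MDRD alternatives, no measured urinary
  CrCL.
- The standard-dose table is reconstructed from its median behaviour, not
  from a published table.
- Synthetic mortality is illustrative; no causal reading of band-mortality
  odds ratios is supported, in the simulation or otherwise.
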