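# pipertdm

Personalized dosing of piperacillin by continuous infusion for critically
ill patients with sepsis: clearance-predicted empiric dosing, therapeutic
drug monitoring (TDM) adjustment, and exposure-band evaluation, with a
synthetic ICU cohort generator for end-to-end validation.

## The problem

β-lactam efficacy tracks the time free drug spends above the pathogen MIC
(fT>MIC). Under continuous infusion a one-compartment model gives a
steady-state plateau

```
c_ss = daily_dose / (24 h × CL)
```

independent of the volume of distribution, and the observed clearance is
recovered from a measured level by the inverse relation
`CL = dose / (24 · c)`. The therapeutic window is **32–64 mg/L** (2–4× the
Pseudomonas aeruginosa MIC breakpoint of 16 mg/L); 64–96 mg/L is
moderately high and >96 mg/L potentially harmful. Critically ill patients
show wide between-patient clearance variability, so the package implements
the personalized strategy:

1. **Empiric dosing** — estimate creatinine clearance (Cockcroft–Gault),
   predict piperacillin clearance by a configurable linear renal-scaling
   model (non-renal floor + slope × CrCL, plus sieving × effluent flow under
   CRRT), and choose `daily_dose = 48 mg/L × CL_pred × 24 h` (mid-window
   target, rounded to 500 mg, after a 2000 mg/15 min loading dose).
2. **TDM adjustment** — when a steady-state level falls outside 32–64 mg/L,
   rescale the dose proportionally (`dose × 48 / c_obs`), re-sampling 24 h
   after each change.
3. **Evaluation** — exposure-band distributions, fT>MIC attainment,
   median-ratio bias/precision of clearance prediction, and band-by-outcome
   odds ratios with Woolf confidence intervals
   (`CI = exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`), including the counterfactual
   plateau a guideline standard dose would have produced at the observed
   clearance.

The synthetic cohort generator draws virtual patients (median age 75 y,
weight 78 kg, CrCL ≈ 47 mL/min, 18% on renal replacement therapy),
log-normal clearance variability (ω = 0.4) and proportional assay noise
(CV = 0.10), so every pipeline stage is testable with known ground truth.

## Worked example

```bash
python examples/empiric_dosing.py
```

```
CrCL (Cockcroft-Gault):     59.7 mL/min
predicted clearance:        9.74 L/h (nonrenal 3.0 + renal 6.74)
loading dose:               2000 mg over 15 min
empiric daily dose:         11000 mg/24 h
implied plateau:            47.0 mg/L (target window 32-64 mg/L)
```

A 75-year-old, 78 kg male with serum creatinine 1.18 mg/dL gets an
11,000 mg/day infusion whose predicted plateau (47 mg/L) sits mid-window.
The end-to-end simulation (`python examples/synthetic_study.py`, 500
virtual patients, seed 42) prints:

```
500 patients, 803 concentration observations
  software-guided empiric           therapeutic  59.6%   >96 mg/L  5.2%
  after TDM adjustment              therapeutic  95.8%   >96 mg/L  0.0%
  standard dosing (counterfactual)  therapeutic  51.0%   >96 mg/L  4.8%
clearance prediction: r2 = 0.529, bias = +0.018, precision = 1.018
```

Clearance-guided empiric dosing beats flat standard dosing on therapeutic
attainment, and TDM adjustment then moves nearly all patients into the
window while eliminating potentially harmful levels — the directional
behaviour the strategy is designed to produce. `examples/tdm_adjustment.py`
and `examples/exposure_evaluation.py` walk through a single adjustment and
the count-table statistics.

A thin CLI mirrors the library: `tdm-pip dose --crcl 47`,
`tdm-pip adjust --daily-dose 8000 --conc 96`,
`tdm-pip simulate --n 179 --seed 42`, `tdm-pip evaluate --observations
obs.csv --out summary.json`.

## Layout

- `src/pipertdm/pk.py` — one-compartment continuous-infusion model
- `src/pipertdm/renal.py` — Cockcroft–Gault and clearance prediction
- `src/pipertdm/dosing.py` — empiric, standard and TDM-adjusted regimens
- `src/pipertdm/exposure.py` — bands, attainment, bias/precision, odds ratios
- `src/pipertdm/cohort.py` — synthetic cohorts and the full study loop
- `src/pipertdm/config.py`, `io.py`, `cli.py` — configuration, tabular I/O, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
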