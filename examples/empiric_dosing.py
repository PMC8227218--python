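"""Empiric continuous-infusion dose from renal function.

A 75-year-old, 78 kg male with serum creatinine 1.18 mg/dL: estimate
creatinine clearance (Cockcroft-Gault), predict piperacillin clearance,
and choose the empiric daily dose targeting the middle of the 32-64 mg/L
therapeutic window.
"""

from pipertdm import (
    RenalStatus,
    cockcroft_gault,
    empiric_regimen,
    predict_clearance,
    steady_state_concentration,
)

crcl = cockcroft_gault(age=75, weight=78, scr=1.18, sex="male")
pred = predict_clearance(RenalStatus(crcl=crcl))
regimen = empiric_regimen(pred.cl_pred)
css = steady_state_concentration(regimen, pred.cl_pred)

print(f"CrCL (Cockcroft-Gault):     {crcl:.1f} mL/min")
print(f"predicted clearance:        {pred.cl_pred:.2f} L/h "
      f"(nonrenal {pred.components['nonrenal']:.1f} + renal {pred.components['renal']:.2f})")
print(f"loading dose:               {regimen.loading_dose:.0f} mg over "
      f"{60 * regimen.loading_duration:.0f} min")
print(f"empiric daily dose:         {regimen.daily_dose:.0f} mg/24 h")
print(f"implied plateau:            {css:.1f} mg/L (target window 32-64 mg/L)")
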