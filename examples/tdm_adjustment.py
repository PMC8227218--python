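"""TDM-guided dose adjustment on a patient whose true clearance is lower
than predicted.

The empiric regimen is chosen from the predicted clearance; the measured
steady-state level comes from the (here, known) true clearance. One
proportional adjustment brings the plateau back into the therapeutic
window.
"""

from pipertdm import (
    DosingPolicy,
    clearance_from_observation,
    empiric_regimen,
    steady_state_concentration,
    tdm_adjust,
)

policy = DosingPolicy()
cl_pred, cl_true = 8.3, 4.5  # L/h; prediction misses the true clearance

regimen = empiric_regimen(cl_pred, policy)
c_obs = steady_state_concentration(regimen, cl_true)
print(f"empiric dose {regimen.daily_dose:.0f} mg/24 h -> measured level {c_obs:.1f} mg/L")
print(f"back-calculated clearance: "
      f"{clearance_from_observation(regimen.daily_dose, c_obs):.2f} L/h (true {cl_true})")

adjusted = tdm_adjust(regimen, c_obs, policy)
c_next = steady_state_concentration(adjusted, cl_true)
print(f"adjusted dose {adjusted.daily_dose:.0f} mg/24 h -> next plateau {c_next:.1f} mg/L")
in_window = policy.target_low <= c_next <= policy.target_high
print(f"inside 32-64 mg/L window: {in_window}")
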