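"""Empiric, standard and TDM-adjusted continuous-infusion regimens.

The personalized strategy: a fixed loading dose (2000 mg over 15 min)
followed immediately by a continuous infusion whose daily dose is chosen
from the predicted clearance so that the plateau lands mid-band
(48 mg/L, the centre of the 32-64 mg/L therapeutic window); a
steady-state level drawn within 24-48 h then drives proportional
TDM adjustment whenever the level falls outside the window.

The comparator is a continuous infusion of guideline standard doses
banded on creatinine clearance; its counterfactual plateau is predicted
from each patient's observed clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pk import DoseRegimen, steady_state_concentration
from .renal import RenalStatus, RRTModality


@dataclass(frozen=True)
class DosingPolicy:
    """Targets and practical constraints for dose selection.

    Doses are rounded to practical vial-size increments (500 mg) and
    clipped to a plausible daily range.
    """

    target_low: float = 32.0
    target_high: float = 64.0
    target_mid: float = 48.0
    rounding_increment: float = 500.0
    max_daily_dose: float = 16000.0
    min_daily_dose: float = 2000.0
    loading_dose: float = 2000.0
    loading_duration: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.target_low < self.target_mid < self.target_high:
            raise ValueError(
                "targets must satisfy 0 < target_low < target_mid < target_high"
            )
        if not self.rounding_increment > 0:
            raise ValueError("rounding_increment must be positive")
        if not 0 < self.min_daily_dose <= self.max_daily_dose:
            raise ValueError("need 0 < min_daily_dose <= max_daily_dose")


def round_to_increment(dose: float, increment: float) -> float:
    """Round a dose to the nearest increment; ties round up."""
    return math.floor(dose / increment + 0.5) * increment


def _finalize_dose(raw_daily: float, policy: DosingPolicy) -> float:
    dose = round_to_increment(raw_daily, policy.rounding_increment)
    return min(max(dose, policy.min_daily_dose), policy.max_daily_dose)


def empiric_regimen(cl_pred: float, policy: DosingPolicy | None = None) -> DoseRegimen:
    """Software-guided empiric regimen from predicted clearance.

    daily_dose = target_mid * cl_pred * 24 h, rounded and clipped; the
    implied plateau sits within the therapeutic window whenever rounding
    and clipping permit.
    """
    policy = policy or DosingPolicy()
    if not cl_pred > 0:
        raise ValueError(f"predicted clearance must be positive, got {cl_pred}")
    daily = _finalize_dose(policy.target_mid * cl_pred * 24.0, policy)
    return DoseRegimen(
        daily_dose=daily,
        loading_dose=policy.loading_dose,
        loading_duration=policy.loading_duration,
    )


#: Guideline standard continuous-infusion daily doses (mg/24 h), banded on
#: CrCL (mL/min) for patients without RRT; flat doses per RRT modality.
#: Bands are half-open [low, high). This table is a reconstruction anchored
#: to the predicted standard median of 12,000 mg/day at CrCL ~47 mL/min and
#: is user-overridable.
DEFAULT_STANDARD_TABLE = {
    "crcl_bands": [(0.0, 20.0, 4000.0), (20.0, 40.0, 8000.0), (40.0, math.inf, 12000.0)],
    "crrt": 8000.0,
    "ihd": 4000.0,
}


def _validate_table(table: dict) -> None:
    bands = sorted(table["crcl_bands"])
    if not bands:
        raise ValueError("standard dose table has no CrCL bands")
    if bands[0][0] != 0.0 or bands[-1][1] != math.inf:
        raise ValueError("CrCL bands must cover [0, inf)")
    for (lo1, hi1, _), (lo2, _hi2, _) in zip(bands, bands[1:]):
        if hi1 != lo2:
            raise ValueError(
                f"CrCL bands must tile without gaps or overlaps; {hi1} != {lo2}"
            )
        if lo1 >= hi1:
            raise ValueError("each CrCL band needs low < high")
    for key in ("crrt", "ihd"):
        if key not in table or table[key] <= 0:
            raise ValueError(f"standard dose table missing positive {key!r} dose")


def standard_regimen(
    status: RenalStatus, table: dict | None = None, policy: DosingPolicy | None = None
) -> DoseRegimen:
    """Guideline standard-dose continuous infusion for a renal status."""
    table = table or DEFAULT_STANDARD_TABLE
    policy = policy or DosingPolicy()
    _validate_table(table)
    if status.rrt_modality is RRTModality.CRRT:
        daily = table["crrt"]
    elif status.rrt_modality is RRTModality.IHD:
        daily = table["ihd"]
    else:
        daily = None
        for lo, hi, dose in table["crcl_bands"]:
            if lo <= status.crcl < hi:
                daily = dose
                break
        if daily is None:  # unreachable with a validated table
            raise ValueError(f"no CrCL band covers {status.crcl}")
    return DoseRegimen(
        daily_dose=daily,
        loading_dose=policy.loading_dose,
        loading_duration=policy.loading_duration,
    )


def counterfactual_concentration(standard: DoseRegimen, cl_obs: float) -> float:
    """Plateau the standard regimen would have produced at the observed
    clearance: steady_state_concentration(standard, cl_obs)."""
    return steady_state_concentration(standard, cl_obs)


def tdm_adjust(
    current: DoseRegimen, c_obs: float, policy: DosingPolicy | None = None
) -> DoseRegimen:
    """Proportional TDM dose adjustment.

    In-window observations leave the regimen unchanged. Otherwise, linear
    PK makes the plateau proportional to dose, so the new daily dose is
    current * target_mid / c_obs (rounded, clipped).
    """
    policy = policy or DosingPolicy()
    if not c_obs > 0:
        raise ValueError(f"observed concentration must be positive, got {c_obs}")
    if not current.daily_dose > 0:
        raise ValueError("current regimen has no maintenance dose to scale")
    if policy.target_low <= c_obs <= policy.target_high:
        return current
    new_daily = _finalize_dose(current.daily_dose * policy.target_mid / c_obs, policy)
    return current.with_daily_dose(new_daily)
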