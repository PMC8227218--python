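"""Configuration schema, loading and validation.

Configuration files are YAML or JSON. Unknown keys are rejected so a
typo never silently falls back to a default. Units are fixed by the
schema: doses in mg, clearances in L/h, CrCL in mL/min, concentrations
in mg/L, times in h.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import CohortConfig, MortalityModel
from .dosing import DosingPolicy
from .renal import ClearanceModel


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PKSection(_StrictModel):
    cl_nonrenal_L_h: float = Field(3.0, gt=0)
    renal_slope_L_h_per_mL_min: float = Field(0.113, ge=0)
    v_L_per_kg: float = Field(0.25, gt=0)


class RRTSection(_StrictModel):
    sieving_coefficient: float = Field(0.8, ge=0, le=1)
    default_effluent_L_h: float = Field(2.0, ge=0)


class CGSection(_StrictModel):
    female_factor: float = Field(0.85, gt=0, le=1)


class TargetsSection(_StrictModel):
    target_low_mg_L: float = Field(32.0, gt=0)
    target_high_mg_L: float = Field(64.0, gt=0)
    target_mid_mg_L: float = Field(48.0, gt=0)
    mic_breakpoint_mg_L: float = Field(16.0, gt=0)
    rounding_increment_mg: float = Field(500.0, gt=0)
    max_daily_dose_mg: float = Field(16000.0, gt=0)
    min_daily_dose_mg: float = Field(2000.0, gt=0)
    loading_dose_mg: float = Field(2000.0, ge=0)
    loading_duration_h: float = Field(0.25, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "TargetsSection":
        if not self.target_low_mg_L < self.target_mid_mg_L < self.target_high_mg_L:
            raise ValueError(
                "targets must satisfy target_low_mg_L < target_mid_mg_L "
                "< target_high_mg_L"
            )
        if self.min_daily_dose_mg > self.max_daily_dose_mg:
            raise ValueError("min_daily_dose_mg must be <= max_daily_dose_mg")
        return self


class StandardDoseSection(_StrictModel):
    """CrCL-banded guideline doses; bands are [low, high) and must tile
    [0, inf). ``high`` null/absent in the last band means unbounded."""

    crcl_bands: list[tuple[float, float | None, float]] = Field(
        default_factory=lambda: [(0.0, 20.0, 4000.0), (20.0, 40.0, 8000.0), (40.0, None, 12000.0)]
    )
    crrt_mg: float = Field(8000.0, gt=0)
    ihd_mg: float = Field(4000.0, gt=0)

    def as_table(self) -> dict:
        bands = [
            (lo, math.inf if hi is None else hi, dose) for lo, hi, dose in self.crcl_bands
        ]
        return {"crcl_bands": bands, "crrt": self.crrt_mg, "ihd": self.ihd_mg}


class CohortSection(_StrictModel):
    n_patients: int = Field(179, ge=1)
    seed: int = 0
    omega_cl: float = Field(0.4, ge=0)
    assay_cv: float = Field(0.10, ge=0)
    crrt_fraction: float = Field(0.10, ge=0, le=1)
    ihd_fraction: float = Field(0.08, ge=0, le=1)
    male_fraction: float = Field(0.64, ge=0, le=1)
    septic_shock_fraction: float = Field(0.30, ge=0, le=1)
    sampling_interval_h: float = Field(24.0, gt=0)
    max_observations: int = Field(6, ge=1)


class RunConfig(_StrictModel):
    """Merged configuration for all pipeline stages."""

    pk: PKSection = Field(default_factory=PKSection)
    rrt: RRTSection = Field(default_factory=RRTSection)
    cg: CGSection = Field(default_factory=CGSection)
    targets: TargetsSection = Field(default_factory=TargetsSection)
    standard_doses: StandardDoseSection = Field(default_factory=StandardDoseSection)
    cohort: CohortSection = Field(default_factory=CohortSection)

    def dosing_policy(self) -> DosingPolicy:
        t = self.targets
        return DosingPolicy(
            target_low=t.target_low_mg_L,
            target_high=t.target_high_mg_L,
            target_mid=t.target_mid_mg_L,
            rounding_increment=t.rounding_increment_mg,
            max_daily_dose=t.max_daily_dose_mg,
            min_daily_dose=t.min_daily_dose_mg,
            loading_dose=t.loading_dose_mg,
            loading_duration=t.loading_duration_h,
        )

    def clearance_model(self) -> ClearanceModel:
        return ClearanceModel(
            cl_nonrenal=self.pk.cl_nonrenal_L_h,
            renal_slope=self.pk.renal_slope_L_h_per_mL_min,
            sieving_coefficient=self.rrt.sieving_coefficient,
        )

    def cohort_config(self, seed: int | None = None) -> CohortConfig:
        c = self.cohort
        return CohortConfig(
            n_patients=c.n_patients,
            seed=c.seed if seed is None else seed,
            male_fraction=c.male_fraction,
            crrt_fraction=c.crrt_fraction,
            ihd_fraction=c.ihd_fraction,
            crrt_effluent_L_h=self.rrt.default_effluent_L_h,
            septic_shock_fraction=c.septic_shock_fraction,
            omega_cl=c.omega_cl,
            assay_cv=c.assay_cv,
            v_per_kg=self.pk.v_L_per_kg,
            sampling_interval_h=c.sampling_interval_h,
            max_observations=c.max_observations,
            mortality=MortalityModel(),
            clearance_model=self.clearance_model(),
        )

    def standard_table(self) -> dict:
        return self.standard_doses.as_table()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    ``None`` or an empty file yields all defaults. Schema violations
    raise ``ValueError`` naming the offending key.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return RunConfig()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries the key path
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc
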