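"""Tabular input/output for observations, cohorts and summaries.

CSV dialect: comma-separated, mandatory header row, "." decimal
separator (a "," decimal in a numeric cell is normalized on read).
Concentrations are stored at full precision; any rounding happens only
at report rendering.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

OBSERVATION_COLUMNS = ["patient_id", "phase", "time_h", "daily_dose_mg", "c_pip_mg_L"]
OPTIONAL_COLUMNS = ["band", "outcome"]


def _to_float(value, column: str, row: int) -> float:
    if isinstance(value, str):
        value = value.strip().replace(",", ".")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: non-numeric value {value!r} in column {column!r}")


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation table, validating schema row by row.

    Required columns: patient_id, phase, time_h, daily_dose_mg,
    c_pip_mg_L; optional: band, outcome. Errors cite the offending
    1-based data row.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str)
    out["phase"] = df["phase"].astype(str)
    for col in ("time_h", "daily_dose_mg", "c_pip_mg_L"):
        out[col] = [
            _to_float(v, col, i + 1) for i, v in enumerate(df[col].tolist())
        ]
    for i, c in enumerate(out["c_pip_mg_L"]):
        if not c > 0:
            raise ValueError(f"row {i + 1}: non-positive concentration {c}")
        if out["time_h"].iloc[i] < 0 or out["daily_dose_mg"].iloc[i] < 0:
            raise ValueError(f"row {i + 1}: negative time or dose")
    for col in OPTIONAL_COLUMNS:
        if col in df.columns:
            out[col] = df[col]
    return out


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table at full precision (round-trip stable)."""
    df.to_csv(path, index=False, float_format="%.17g")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_summary(record: dict, path: str | Path) -> None:
    """Write a summary record as JSON (band tables keyed lt16/b16_32/...)."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(record), indent=2) + "\n", encoding="utf-8")


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
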