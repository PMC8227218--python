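"""Exposure-band classification and evaluation statistics.

Steady-state piperacillin concentrations are graded against the
therapeutic window of 32-64 mg/L, i.e. two to four times the Pseudomonas
aeruginosa MIC breakpoint of 16 mg/L: concentrations of 64-96 mg/L are
moderately high and >96 mg/L potentially harmful.  Under continuous
infusion at steady state, "100% fT > k x MIC" (free drug above k times the
MIC for the whole dosing interval) reduces to the plateau exceeding
k x MIC.

The module also provides the prediction-error summaries (median of the
predicted/observed ratio: bias = median ratio - 1, precision = median
magnitude of the ratio) and unadjusted 2x2 odds ratios with Woolf
(log-normal) confidence intervals used to relate exposure bands to
hospital mortality.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: Band edges in mg/L: (0,16), [16,32), [32,64], (64,96], (96,inf).
#: The therapeutic band [32, 64] is closed on both sides, so a reading of
#: exactly 64 mg/L counts as therapeutic.
BAND_EDGES = (16.0, 32.0, 64.0, 96.0)


class ExposureBand(enum.Enum):
    LT16 = "lt16"
    B16_32 = "b16_32"
    B32_64 = "b32_64"
    B64_96 = "b64_96"
    GT96 = "gt96"


#: Lower edge of each band (mg/L); used for threshold ("> edge") arithmetic.
BAND_LOWER = {
    ExposureBand.LT16: 0.0,
    ExposureBand.B16_32: 16.0,
    ExposureBand.B32_64: 32.0,
    ExposureBand.B64_96: 64.0,
    ExposureBand.GT96: 96.0,
}

BAND_ORDER = list(ExposureBand)

#: Human-readable labels matching the reporting convention.
BAND_LABELS = {
    ExposureBand.LT16: "<16",
    ExposureBand.B16_32: "16-32",
    ExposureBand.B32_64: "32-64",
    ExposureBand.B64_96: "64-96",
    ExposureBand.GT96: ">96",
}


def classify_band(c_pip: float, edges: tuple = BAND_EDGES) -> ExposureBand:
    """Assign a positive concentration to its exposure band.

    Boundary convention: 16 -> 16-32 band, 32 and 64 -> therapeutic band,
    96 -> moderately-high band (therapeutic band closed, neighbours
    half-open accordingly).
    """
    if not c_pip > 0:
        raise ValueError(f"concentration must be positive, got {c_pip}")
    e1, e2, e3, e4 = edges
    if c_pip < e1:
        return ExposureBand.LT16
    if c_pip < e2:
        return ExposureBand.B16_32
    if c_pip <= e3:
        return ExposureBand.B32_64
    if c_pip <= e4:
        return ExposureBand.B64_96
    return ExposureBand.GT96


@dataclass(frozen=True)
class BandDistribution:
    """Counts and fractions of observations per exposure band."""

    counts: dict
    n: int

    @property
    def fractions(self) -> dict:
        return {b: self.counts[b] / self.n for b in BAND_ORDER}

    def fraction_above(self, edge: float) -> float:
        """Fraction of observations above a band edge (16, 32, 64 or 96)."""
        if edge not in BAND_LOWER.values():
            raise ValueError(f"{edge} is not a band edge")
        total = sum(self.counts[b] for b in BAND_ORDER if BAND_LOWER[b] >= edge)
        return total / self.n

    @classmethod
    def from_counts(cls, counts: dict) -> "BandDistribution":
        counts = {b: int(counts[b]) for b in BAND_ORDER}
        return cls(counts=counts, n=sum(counts.values()))


def band_distribution(observations, n_total: int | None = None) -> BandDistribution:
    """Band counts and fractions for a series of concentrations.

    ``n_total`` (default: series length) is a validation hook for
    one-observation-per-patient mode; fractions are always over the series
    length so they sum to 1.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation series")
    if n_total is not None and n_total < obs.size:
        raise ValueError("n_total must be >= number of observations")
    counts = {b: 0 for b in BAND_ORDER}
    for c in obs:
        counts[classify_band(float(c))] += 1
    return BandDistribution(counts=counts, n=int(obs.size))


def ft_above_mic(css: float, mic: float = 16.0, multiple: float = 1.0) -> bool:
    """Whether 100% fT > multiple x MIC is attained at steady state.

    For continuous infusion at steady state this is simply
    css > multiple * mic.
    """
    if not mic > 0:
        raise ValueError("mic must be positive")
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    return css > multiple * mic


def attainment_fraction(
    observations, mic: float = 16.0, multiple: float = 1.0
) -> float:
    """Cohort fraction attaining 100% fT > multiple x MIC."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation series")
    return float(np.mean(obs > multiple * mic))


@dataclass(frozen=True)
class BiasPrecision:
    """Median-ratio prediction-error summary.

    ``bias`` is the median of the predicted/observed ratios minus 1;
    ``precision`` is the median magnitude of the ratio. With strictly
    positive series, precision = bias + 1.
    """

    bias: float
    precision: float
    n: int


def bias_precision(pred, obs) -> BiasPrecision:
    """Median relative-error bias and precision for paired series.

    r_i = pred_i / obs_i; bias = median(r) - 1; precision = median(|r|).
    Medians are reported because clearance ratios in critically ill
    cohorts are not normally distributed.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D with equal length")
    if pred.size < 1:
        raise ValueError("need at least one pair")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("all values must be positive")
    r = pred / obs
    return BiasPrecision(
        bias=float(np.median(r) - 1.0),
        precision=float(np.median(np.abs(r))),
        n=int(pred.size),
    )


@dataclass(frozen=True)
class ORResult:
    """Unadjusted odds ratio for a 2x2 table with Woolf confidence interval.

    Cells: a = exposed-dead, b = exposed-alive, c = reference-dead,
    d = reference-alive.
    """

    a: int
    b: int
    c: int
    d: int
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float = 0.05


def odds_ratio_woolf(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, haldane: bool = False
) -> ORResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log-SE confidence interval.

    CI = exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d));
    the p-value is the two-sided Wald test on the log odds ratio.

    Zero cells are an error unless ``haldane=True``, which applies the
    Haldane-Anscombe +0.5 correction to every cell.

    Raises
    ------
    ValueError
        If any count is negative, or any cell is zero without ``haldane``.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be >= 0")
    if haldane:
        cells = [x + 0.5 for x in cells]
    elif any(x == 0 for x in cells):
        raise ValueError(
            "2x2 table has a zero cell; pass haldane=True to apply the "
            "Haldane-Anscombe +0.5 correction"
        )
    fa, fb, fc, fd = (float(x) for x in cells)
    or_value = (fa * fd) / (fb * fc)
    se = math.sqrt(1.0 / fa + 1.0 / fb + 1.0 / fc + 1.0 / fd)
    z = norm.ppf(1.0 - alpha / 2.0)
    log_or = math.log(or_value)
    p_value = 2.0 * norm.sf(abs(log_or) / se)
    return ORResult(
        a=a,
        b=b,
        c=c,
        d=d,
        or_value=or_value,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p_value),
        alpha=alpha,
    )


def mortality_by_band(
    bands, outcomes, reference: ExposureBand = ExposureBand.B32_64
) -> dict:
    """Per-band mortality rates and odds ratios versus the therapeutic band.

    Parameters
    ----------
    bands : sequence of ExposureBand
        One band per patient.
    outcomes : sequence of int
        1 = died, 0 = survived, aligned with ``bands``.
    reference : ExposureBand
        Reference band for the odds ratios (default: therapeutic).

    Returns
    -------
    dict
        Per band: ``{"deaths", "n", "rate"}`` (``rate`` is None for empty
        bands) plus ``"or"`` — an :class:`ORResult` versus the reference,
        or None when the band is the reference, empty, or the 2x2 table
        has a zero cell.
    """
    bands = list(bands)
    outcomes = [int(o) for o in outcomes]
    if len(bands) != len(outcomes):
        raise ValueError("bands and outcomes must have equal length")
    if not all(o in (0, 1) for o in outcomes):
        raise ValueError("outcomes must be 0 or 1")
    deaths = {band: 0 for band in BAND_ORDER}
    totals = {band: 0 for band in BAND_ORDER}
    for band, out in zip(bands, outcomes):
        totals[band] += 1
        deaths[band] += out
    ref_dead = deaths[reference]
    ref_alive = totals[reference] - ref_dead
    table = {}
    for band in BAND_ORDER:
        n = totals[band]
        entry = {
            "deaths": deaths[band],
            "n": n,
            "rate": deaths[band] / n if n else None,
            "or": None,
        }
        if band is not reference and n > 0:
            a, b = deaths[band], n - deaths[band]
            if min(a, b, ref_dead, ref_alive) > 0:
                entry["or"] = odds_ratio_woolf(a, b, ref_dead, ref_alive)
        table[band] = entry
    return table
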