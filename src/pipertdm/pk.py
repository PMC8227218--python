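"""One-compartment pharmacokinetics for continuous-infusion piperacillin.

Piperacillin is hydrophilic, has a small volume of distribution, low protein
binding and predominantly renal elimination, so a one-compartment model with
first-order elimination is adequate for serum-concentration analysis under
continuous infusion.  At steady state under a constant infusion rate the
plateau concentration is

    css = daily_dose / (24 h * CL)

independent of the volume of distribution, and the observed clearance can be
back-calculated from a measured steady-state concentration by inverting the
same relation.  The transient solution (loading infusion superposed on the
maintenance infusion) is provided to verify the closed form and to simulate
the timing of therapeutic-drug-monitoring samples.

Units throughout: mass in mg, volume in L, time in h, concentration in mg/L,
clearance in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class PKProfile:
    """A patient's disposition parameters.

    Parameters
    ----------
    cl : float
        Total piperacillin clearance, L/h. Must be positive.
    v : float
        Volume of distribution, L. Must be positive. Only the transient
        behaviour depends on ``v``; the steady-state plateau does not.
    """

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not self.cl > 0:
            raise ValueError(f"clearance must be positive, got {self.cl}")
        if not self.v > 0:
            raise ValueError(f"volume of distribution must be positive, got {self.v}")

    @property
    def k(self) -> float:
        """First-order elimination rate constant cl / v, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseRegimen:
    """Loading dose plus constant-rate continuous infusion.

    The default loading dose is 2000 mg infused over 15 min, followed by the
    continuous maintenance infusion delivering ``daily_dose`` mg per 24 h.
    """

    daily_dose: float
    loading_dose: float = 2000.0
    loading_duration: float = 0.25

    def __post_init__(self) -> None:
        if self.daily_dose < 0:
            raise ValueError(f"daily_dose must be >= 0, got {self.daily_dose}")
        if self.loading_dose < 0:
            raise ValueError(f"loading_dose must be >= 0, got {self.loading_dose}")
        if not self.loading_duration > 0:
            raise ValueError(
                f"loading_duration must be positive, got {self.loading_duration}"
            )

    @property
    def infusion_rate(self) -> float:
        """Maintenance infusion rate, mg/h (= daily_dose / 24, exact)."""
        return self.daily_dose / 24.0

    def with_daily_dose(self, daily_dose: float) -> "DoseRegimen":
        return replace(self, daily_dose=daily_dose)


def steady_state_concentration(regimen: DoseRegimen, cl: float) -> float:
    """Plateau concentration under constant-rate infusion, mg/L.

    css = daily_dose / (24 * cl); independent of the volume of distribution.

    Raises
    ------
    ValueError
        If ``cl`` is not positive.
    """
    if not cl > 0:
        raise ValueError(f"clearance must be positive, got {cl}")
    return regimen.daily_dose / (24.0 * cl)


def clearance_from_observation(daily_dose: float, c_pip: float) -> float:
    """Observed clearance from a steady-state concentration, L/h.

    CL = daily_dose / (24 * c_pip). Round-trips with
    :func:`steady_state_concentration` to machine precision.

    Raises
    ------
    ValueError
        If ``c_pip`` is not positive or ``daily_dose`` is negative.
    """
    if not c_pip > 0:
        raise ValueError(f"observed concentration must be positive, got {c_pip}")
    if daily_dose < 0:
        raise ValueError(f"daily_dose must be >= 0, got {daily_dose}")
    return daily_dose / (24.0 * c_pip)


def _zero_order_infusion(
    rate: float, duration: float, k: float, cl: float, t: np.ndarray
) -> np.ndarray:
    """Concentration contribution of one zero-order infusion starting at t=0.

    During the infusion: (rate/cl) * (1 - exp(-k t)); afterwards the value at
    end of infusion decays mono-exponentially.
    """
    t_on = np.clip(t, 0.0, duration)
    t_off = np.clip(t - duration, 0.0, None)
    return (rate / cl) * (1.0 - np.exp(-k * t_on)) * np.exp(-k * t_off)


def concentration_time_course(
    regimen: DoseRegimen, pk: PKProfile, times: np.ndarray
) -> np.ndarray:
    """Serum concentration at each time point, mg/L.

    Superposition of the finite loading infusion and the maintenance
    infusion, both starting at t = 0. As t grows the value converges to
    :func:`steady_state_concentration`.

    Parameters
    ----------
    times : array-like
        Strictly increasing, non-negative time grid in hours.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    k = pk.k
    c = _zero_order_infusion(regimen.infusion_rate, np.inf, k, pk.cl, t)
    if regimen.loading_dose > 0:
        load_rate = regimen.loading_dose / regimen.loading_duration
        c = c + _zero_order_infusion(load_rate, regimen.loading_duration, k, pk.cl, t)
    return c


def concentration_after_rate_change(
    c0: float, regimen: DoseRegimen, pk: PKProfile, dt: float
) -> float:
    """Concentration ``dt`` hours after switching to a new maintenance rate.

    Linear one-compartment relaxation from the pre-switch concentration
    ``c0`` toward the new plateau: css + (c0 - css) * exp(-k dt).
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    css = steady_state_concentration(regimen, pk.cl)
    return css + (c0 - css) * np.exp(-pk.k * dt)
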