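"""Independent numeric oracle for the one-compartment closed form.

Integrates dC/dt = rate_in(t)/V - (CL/V) * C with scipy's adaptive RK,
split at the end of the loading infusion so the rate discontinuity never
crosses an integration step. Deliberately independent of the package's
closed-form solution.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration(regimen, pk, times):
    """Numerically integrated concentration at each requested time."""
    times = np.asarray(times, dtype=float)
    k = pk.cl / pk.v
    maint = regimen.daily_dose / 24.0
    load = regimen.loading_dose / regimen.loading_duration if regimen.loading_dose else 0.0
    dur = regimen.loading_duration

    def rhs(rate):
        return lambda t, y: rate / pk.v - k * y

    out = np.empty_like(times)
    c0, t0 = 0.0, 0.0
    # segment 1: loading + maintenance until end of loading
    seg1 = times[times <= dur]
    if seg1.size or times.size:
        sol = solve_ivp(
            rhs(maint + load), (0.0, dur), [0.0], t_eval=seg1 if seg1.size else None,
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        out[: seg1.size] = sol.y[0][: seg1.size] if seg1.size else []
        c0, t0 = float(sol.y[0][-1]), dur
    seg2 = times[times > dur]
    if seg2.size:
        sol = solve_ivp(
            rhs(maint), (t0, float(seg2[-1])), [c0], t_eval=seg2,
            rtol=1e-10, atol=1e-12,
        )
        out[seg1.size:] = sol.y[0]
    return out
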