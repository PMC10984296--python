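"""Independent numerical oracles for the closed-form model.

The one-compartment system is integrated as an ODE (gut + central amounts
plus a cumulative-AUC state) with tight tolerances, piecewise between
event boundaries so infusion on/off switches and oral boluses are exact.
Kept deliberately independent of the analytic code under test.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from neopk.model import DosingEvent, Route, StructuralParameters


def ode_profile(params: StructuralParameters, events: list[DosingEvent],
                times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (concentrations, cumulative AUC from 0) at the given times."""
    times = np.asarray(times, dtype=float)
    k = params.cl / params.v
    ka = params.ka

    breaks = {0.0}
    for ev in events:
        breaks.add(ev.start_time)
        if ev.route is Route.IV_INFUSION:
            breaks.add(ev.start_time + ev.duration)
    breaks |= set(times.tolist())
    grid = sorted(b for b in breaks if b >= 0.0)

    def infusion_rate(t: float) -> float:
        r = 0.0
        for ev in events:
            if ev.route is Route.IV_INFUSION:
                if ev.start_time <= t < ev.start_time + ev.duration:
                    r += ev.amount / ev.duration
        return r

    state = np.zeros(3)  # gut amount, central amount, cumulative AUC
    sol_at: dict[float, np.ndarray] = {0.0: state.copy()}
    t_prev = grid[0]
    for ev in events:
        if ev.route is Route.ORAL and ev.start_time == t_prev:
            state[0] += ev.amount
    sol_at[t_prev] = state.copy()

    for t_next in grid[1:]:
        rate = infusion_rate((t_prev + t_next) / 2.0)

        def rhs(t, y):
            return [-ka * y[0],
                    params.f * ka * y[0] + rate - k * y[1],
                    y[1] / params.v]

        res = solve_ivp(rhs, (t_prev, t_next), state, method="LSODA",
                        rtol=1e-11, atol=1e-14, dense_output=False)
        state = res.y[:, -1].copy()
        for ev in events:
            if ev.route is Route.ORAL and ev.start_time == t_next:
                state[0] += ev.amount
        sol_at[t_next] = state.copy()
        t_prev = t_next

    conc = np.array([0.0 if t < grid[0] else sol_at[t][1] / params.v
                     for t in times])
    auc = np.array([0.0 if t < grid[0] else sol_at[t][2] for t in times])
    return conc, auc


def grid_search_eta(objective, sd: np.ndarray, n: int = 41,
                    half_width: float = 3.0) -> tuple[np.ndarray, float]:
    """Dense 2-d grid minimisation of a MAP objective over +-half_width SD."""
    g1 = np.linspace(-half_width * sd[0], half_width * sd[0], n)
    g2 = np.linspace(-half_width * sd[1], half_width * sd[1], n)
    best_val = np.inf
    best = np.zeros(2)
    for a in g1:
        for b in g2:
            v = objective(np.array([a, b]))
            if v < best_val:
                best_val = v
                best = np.array([a, b])
    return best, best_val
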