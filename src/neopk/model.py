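"""One-compartment concentration model with analytic dose superposition.

The structural model is a one-compartment disposition model with first-order
elimination (rate constant ``k = CL/V``).  Intravenous infusions enter the
central compartment at a constant rate ``R0 = amount/duration`` and bypass
absorption entirely; oral doses are absorbed first-order with rate constant
``ka`` and bioavailability fixed at 1.  All closed forms are the standard
linear-PK solutions, and multi-dose profiles are obtained by superposition.

Units are fixed package-wide: mg for amounts, L for volumes, h for times,
mg/L for concentrations, h*mg/L for AUCs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Route",
    "DosingEvent",
    "StructuralParameters",
    "concentration_single_event",
    "concentration_profile",
    "auc_interval",
]

#: Relative threshold below which |ka - k| is treated as degenerate and the
#: ka -> k limiting forms are used; avoids catastrophic cancellation in the
#: flip-flop denominator without a visible discontinuity.
KA_K_REL_TOL = 1e-8


class Route(str, Enum):
    """Administration route of a dosing event."""

    IV_INFUSION = "iv_infusion"
    ORAL = "oral"


@dataclass(frozen=True)
class DosingEvent:
    """A single drug administration.

    Parameters
    ----------
    start_time : float
        Hours since the first dose (t=0 at first dose administration).
    amount : float
        Dose amount in mg; strictly positive.
    route : Route
        ``iv_infusion`` (constant-rate infusion) or ``oral``.
    duration : float, optional
        Infusion duration in hours.  Required (and > 0) for IV infusions;
        must be absent for oral doses.
    """

    start_time: float
    amount: float
    route: Route = Route.IV_INFUSION
    duration: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if not (self.amount > 0):
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.route is Route.IV_INFUSION:
            if self.duration is None or not (self.duration > 0):
                raise ValueError(
                    "iv_infusion events require a positive infusion duration"
                )
        elif self.duration is not None:
            raise ValueError("oral events must not carry an infusion duration")

    @property
    def rate(self) -> float:
        """Infusion rate R0 = amount/duration (mg/h); IV events only."""
        if self.route is not Route.IV_INFUSION:
            raise ValueError("rate is defined only for iv_infusion events")
        assert self.duration is not None
        return self.amount / self.duration


@dataclass(frozen=True)
class StructuralParameters:
    """Individual structural PK parameters.

    ``cl`` (clearance, L/h), ``v`` (central volume, L) and ``ka``
    (first-order absorption rate constant, 1/h) must be strictly positive.
    Bioavailability ``f`` is fixed at 1.  The elimination rate constant
    ``k = cl/v`` is always derived, never stored independently.
    """

    cl: float
    v: float
    ka: float
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            if not (getattr(self, name) > 0) or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and > 0, got {getattr(self, name)}")
        if not (0 < self.f <= 1):
            raise ValueError(f"bioavailability f must be in (0, 1], got {self.f}")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl / self.v


def _iv_conc(params: StructuralParameters, amount: float, duration: float,
             tau: np.ndarray) -> np.ndarray:
    """Concentration for one IV infusion at elapsed times tau (vectorised)."""
    k = params.k
    r0 = amount / duration
    c_end = (r0 / params.cl) * -math.expm1(-k * duration)
    # both branches are evaluated before np.where selects; for extreme k the
    # discarded branch can overflow, which is harmless
    with np.errstate(over="ignore"):
        during = (r0 / params.cl) * -np.expm1(-k * np.minimum(tau, duration))
        after = c_end * np.exp(-k * (tau - duration))
    out = np.where(tau <= duration, during, after)
    return np.where(tau < 0, 0.0, out)


def _oral_conc(params: StructuralParameters, amount: float,
               tau: np.ndarray) -> np.ndarray:
    """Concentration for one oral dose at elapsed times tau (vectorised)."""
    k = params.k
    ka = params.ka
    tpos = np.maximum(tau, 0.0)
    if abs(ka - k) < KA_K_REL_TOL * k:
        out = params.f * amount * k * tpos * np.exp(-k * tpos) / params.v
    else:
        coef = params.f * amount * ka / (params.v * (ka - k))
        out = coef * (np.exp(-k * tpos) - np.exp(-ka * tpos))
    return np.where(tau < 0, 0.0, out)


def _iv_cum_auc(params: StructuralParameters, amount: float, duration: float,
                tau: float) -> float:
    """Integral of the single-infusion concentration from elapsed 0 to tau."""
    if tau <= 0:
        return 0.0
    k = params.k
    r0 = amount / duration
    t_in = min(tau, duration)
    # during infusion: (R0/CL) * [t + (e^{-kt} - 1)/k]
    auc = (r0 / params.cl) * (t_in + math.expm1(-k * t_in) / k)
    if tau > duration:
        c_end = (r0 / params.cl) * -math.expm1(-k * duration)
        auc += (c_end / k) * -math.expm1(-k * (tau - duration))
    return auc


def _oral_cum_auc(params: StructuralParameters, amount: float, tau: float) -> float:
    if tau <= 0:
        return 0.0
    k = params.k
    ka = params.ka
    if abs(ka - k) < KA_K_REL_TOL * k:
        # integral of F*D*k*t*e^{-kt}/V dt = (F*D/V) * (1 - e^{-kt}(1+kt)) / k
        return (params.f * amount / params.v) * (
            1.0 - math.exp(-k * tau) * (1.0 + k * tau)
        ) / k
    coef = params.f * amount * ka / (params.v * (ka - k))
    return coef * (-math.expm1(-k * tau) / k + math.expm1(-ka * tau) / ka)


def concentration_single_event(params: StructuralParameters, event: DosingEvent,
                               t: float | np.ndarray) -> float | np.ndarray:
    """Plasma concentration (mg/L) due to one dosing event at time(s) ``t``.

    Times before the event start return exactly 0, which makes superposition
    over a dosing history a plain sum.
    """
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr - event.start_time
    if event.route is Route.IV_INFUSION:
        assert event.duration is not None
        out = _iv_conc(params, event.amount, event.duration, tau)
    else:
        out = _oral_conc(params, event.amount, tau)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def concentration_profile(params: StructuralParameters,
                          events: Sequence[DosingEvent],
                          times: Iterable[float]) -> np.ndarray:
    """Superposed concentration over a dosing history, aligned with ``times``."""
    events = list(events)
    if not events:
        raise ValueError("events must be non-empty")
    t_arr = np.asarray(list(times), dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("times must be finite")
    total = np.zeros_like(t_arr)
    for ev in events:
        total += concentration_single_event(params, ev, t_arr)
    return total


def auc_interval(params: StructuralParameters, events: Sequence[DosingEvent],
                 t0: float, t1: float) -> float:
    """Analytic area under the superposed curve over [t0, t1] (h*mg/L)."""
    events = list(events)
    if not events:
        raise ValueError("events must be non-empty")
    if not (t0 < t1):
        raise ValueError(f"require t0 < t1, got [{t0}, {t1}]")
    total = 0.0
    for ev in events:
        if ev.route is Route.IV_INFUSION:
            assert ev.duration is not None
            total += _iv_cum_auc(params, ev.amount, ev.duration, t1 - ev.start_time)
            total -= _iv_cum_auc(params, ev.amount, ev.duration, t0 - ev.start_time)
        else:
            total += _oral_cum_auc(params, ev.amount, t1 - ev.start_time)
            total -= _oral_cum_auc(params, ev.amount, t0 - ev.start_time)
    return total
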