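"""Secondary (derived) PK parameters for a single IV infusion dose.

All quantities are closed-form one-compartment results anchored at the
subject's first dose, which must be an IV infusion: AUC(0-12) by analytic
integration, AUC(0-inf) = dose/CL (F = 1), Cmax at end of infusion
(the one-compartment IV profile is non-decreasing during the infusion and
non-increasing afterwards, so the maximum sits exactly at the end of
infusion), tmax = infusion duration reported in minutes, Vd = V, CL in
both L/h and mL/min, and t1/2 = ln2 * V / CL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import DosingEvent, Route, StructuralParameters, auc_interval, \
    concentration_single_event

__all__ = ["SecondaryParameters", "derive_secondary"]


@dataclass(frozen=True)
class SecondaryParameters:
    """Per-subject derived PK parameters (single IV dose).

    Units: AUCs in h*mg/L, cmax in mg/L, tmax in minutes, vd in L,
    clearance in L/h and mL/min, half-life in hours.
    """

    auc_0_12: float
    auc_inf: float
    cmax: float
    tmax: float
    vd: float
    cl_lph: float
    cl_mlpm: float
    t_half: float

    def __post_init__(self) -> None:
        if not (self.auc_inf >= self.auc_0_12 > 0):
            raise ValueError("require auc_inf >= auc_0_12 > 0")

    def to_dict(self) -> dict:
        return {"auc_0_12": self.auc_0_12, "auc_inf": self.auc_inf,
                "cmax": self.cmax, "tmax": self.tmax, "vd": self.vd,
                "cl_lph": self.cl_lph, "cl_mlpm": self.cl_mlpm,
                "t_half": self.t_half}


def derive_secondary(params: StructuralParameters,
                     dosing: list[DosingEvent]) -> SecondaryParameters:
    """Derive single-dose secondary parameters from the first dosing event."""
    if not dosing:
        raise ValueError("dosing history is empty")
    first = min(dosing, key=lambda e: e.start_time)
    if first.route is not Route.IV_INFUSION:
        raise ValueError(
            "secondary parameters are defined for IV infusion dosing only; "
            f"first event has route {first.route.value!r}"
        )
    assert first.duration is not None
    single = [DosingEvent(start_time=0.0, amount=first.amount,
                          route=Route.IV_INFUSION, duration=first.duration)]
    auc_0_12 = auc_interval(params, single, 0.0, 12.0)
    auc_inf = params.f * first.amount / params.cl
    cmax = float(concentration_single_event(params, single[0], first.duration))
    tmax_min = first.duration * 60.0
    cl = params.cl
    return SecondaryParameters(
        auc_0_12=auc_0_12,
        auc_inf=auc_inf,
        cmax=cmax,
        tmax=tmax_min,
        vd=params.v,
        cl_lph=cl,
        cl_mlpm=cl * 1000.0 / 60.0,
        t_half=math.log(2.0) * params.v / cl,
    )
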