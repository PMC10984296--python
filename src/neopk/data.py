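"""Subject records and the NONMEM-style CSV dataset dialect.

One row per event.  Columns: ID, TIME (h), AMT (mg), RATE (mg/h), EVID
(1 = dose, 0 = observation), DV (mg/L), MDV, BLQ, LLOQ (mg/L), WT (kg),
PNA (days), CGA (weeks), ROUTE.  RATE together with AMT encodes the
infusion duration (duration = AMT/RATE); oral doses leave RATE empty.
Covariates are repeated on every row of a subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DosingEvent, Route

__all__ = [
    "ConcentrationObservation",
    "SubjectRecord",
    "pna_weeks",
    "ga_from_cga_pna",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV",
                   "BLQ", "LLOQ", "WT", "PNA", "CGA", "ROUTE"]


def pna_weeks(pna_days: float) -> int:
    """Postnatal age in weeks: days / 7 rounded up to the nearest week."""
    return int(math.ceil(pna_days / 7.0))


def ga_from_cga_pna(cga_weeks: float, pna_days: float) -> float:
    """Gestational age (weeks) as corrected gestational age minus postnatal age.

    PNA enters in whole weeks (rounded up), matching the demographic
    convention GA = CGA - PNA used for neonatal cohorts.
    """
    return cga_weeks - pna_weeks(pna_days)


@dataclass(frozen=True)
class ConcentrationObservation:
    """One plasma concentration sample.

    ``value`` is the measured concentration in mg/L (> 0) for quantifiable
    samples; below-limit samples carry ``blq_flag=True``, a NaN value and
    the assay's lower limit of quantification ``lloq``.
    """

    time: float
    value: float
    blq_flag: bool = False
    lloq: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if self.blq_flag:
            if self.lloq is None or not (self.lloq > 0):
                raise ValueError("BLQ observations require a positive lloq")
        else:
            if not (self.value > 0):
                raise ValueError(
                    f"quantifiable observations require value > 0, got {self.value}"
                )


@dataclass
class SubjectRecord:
    """A neonate's covariates, dosing history and concentration observations."""

    subject_id: str
    weight: float
    pna_days: float
    cga_weeks: float
    dosing: list[DosingEvent] = field(default_factory=list)
    observations: list[ConcentrationObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError(f"weight must be > 0 kg, got {self.weight}")
        self.dosing = sorted(self.dosing, key=lambda e: e.start_time)

    @property
    def ga_weeks(self) -> float:
        """Gestational age in weeks (CGA minus PNA in whole weeks)."""
        return ga_from_cga_pna(self.cga_weeks, self.pna_days)

    def usable_observations(self, include_blq: bool = False) -> list[ConcentrationObservation]:
        return [o for o in self.observations if include_blq or not o.blq_flag]


def write_dataset(subjects: list[SubjectRecord], path: str | Path) -> None:
    """Write subjects to the CSV dataset dialect (lossless round-trip)."""
    rows: list[dict] = []
    for s in subjects:
        cov = {"ID": s.subject_id, "WT": s.weight, "PNA": s.pna_days,
               "CGA": s.cga_weeks}
        for ev in s.dosing:
            rate = ev.rate if ev.route is Route.IV_INFUSION else np.nan
            rows.append({**cov, "TIME": ev.start_time, "AMT": ev.amount,
                         "RATE": rate, "EVID": 1, "DV": np.nan, "MDV": 1,
                         "BLQ": 0, "LLOQ": np.nan, "ROUTE": ev.route.value})
        for ob in s.observations:
            rows.append({**cov, "TIME": ob.time, "AMT": np.nan, "RATE": np.nan,
                         "EVID": 0,
                         "DV": np.nan if ob.blq_flag else ob.value,
                         "MDV": 1 if ob.blq_flag else 0,
                         "BLQ": int(ob.blq_flag),
                         "LLOQ": ob.lloq if ob.lloq is not None else np.nan,
                         "ROUTE": ""})
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    # repr gives the shortest round-trip decimal form; pandas' default float
    # formatting truncates below full double precision
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def _row_err(idx: int, msg: str) -> ValueError:
    # idx is the 0-based data row; +2 accounts for the header line
    return ValueError(f"dataset line {idx + 2}: {msg}")


def read_dataset(path: str | Path) -> list[SubjectRecord]:
    """Parse the CSV dataset dialect back into subject records."""
    df = pd.read_csv(path, dtype={"ID": str, "ROUTE": str},
                     float_precision="round_trip")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset {path} missing columns: {sorted(missing)}")

    subjects: dict[str, SubjectRecord] = {}
    for idx, row in df.iterrows():
        sid = row["ID"]
        if sid not in subjects:
            subjects[sid] = SubjectRecord(
                subject_id=sid, weight=float(row["WT"]),
                pna_days=float(row["PNA"]), cga_weeks=float(row["CGA"]))
        subj = subjects[sid]
        evid = int(row["EVID"])
        if evid == 1:
            route_code = str(row["ROUTE"]).strip()
            try:
                route = Route(route_code)
            except ValueError:
                raise _row_err(idx, f"unknown route code {route_code!r}") from None
            if route is Route.IV_INFUSION:
                if pd.isna(row["RATE"]) or not (row["RATE"] > 0):
                    raise _row_err(idx, "iv_infusion dose requires a positive RATE")
                duration = float(row["AMT"]) / float(row["RATE"])
            else:
                duration = None
            if pd.isna(row["AMT"]):
                raise _row_err(idx, "dose row requires AMT")
            subj.dosing.append(DosingEvent(
                start_time=float(row["TIME"]), amount=float(row["AMT"]),
                route=route, duration=duration))
        elif evid == 0:
            blq = bool(int(row["BLQ"])) if not pd.isna(row["BLQ"]) else False
            if not blq and pd.isna(row["DV"]):
                raise _row_err(idx, "observation row requires DV unless BLQ")
            subj.observations.append(ConcentrationObservation(
                time=float(row["TIME"]),
                value=math.nan if blq else float(row["DV"]),
                blq_flag=blq,
                lloq=None if pd.isna(row["LLOQ"]) else float(row["LLOQ"])))
        else:
            raise _row_err(idx, f"unsupported EVID {evid}")
    out = list(subjects.values())
    for s in out:
        s.dosing.sort(key=lambda e: e.start_time)
    return out
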