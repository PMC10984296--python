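"""Cohort-level descriptive statistics: GeoMean, GeoCV, median (range),
and concentration summaries binned by time since the most recent infusion.

GeoMean = exp(mean(ln x)).  GeoCV[%] = 100 * sqrt(exp(s^2) - 1) with s^2
the n-1 sample variance of ln x — the standard summary pair for
lognormally distributed PK parameters.  Summary cells follow a two-thirds
validity rule: GeoMean/GeoCV are reported only when at least two thirds of
the cohort contributed a properly determined value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .data import SubjectRecord
from .model import Route

__all__ = [
    "round_half_up",
    "SamplingWindow",
    "SummaryCell",
    "geomean",
    "geocv_pct",
    "median_range",
    "summary_cell",
    "bin_concentrations",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as summary tables are printed.

    Applied only at serialization/reporting; all computation stays at full
    precision.  Python's builtin round() is banker's rounding and would
    turn a printed 6.98 into 6.97.  The value is first collapsed to 12
    significant digits so that double-precision noise just below a decimal
    tie (e.g. (2.28 + 2.75)/2 = 2.5149999999999997) still rounds as the
    exact tie would.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{float(x):.12g}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SamplingWindow:
    """A sampling window in hours after the start of the most recent infusion."""

    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValueError(f"window {self.label!r}: require lo < hi")


@dataclass(frozen=True)
class SummaryCell:
    """One summary table cell with the two-thirds validity rule applied.

    ``valid`` is True iff n_used >= ceil(2/3 * n_total); when invalid,
    geomean and geocv_pct are None (absent), never zero.
    """

    n_used: int
    n_total: int
    valid: bool
    geomean: float | None
    geocv_pct: float | None
    median: float | None
    range_lo: float | None
    range_hi: float | None


def _as_positive_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("all values must be finite and > 0")
    return arr


def geomean(values: Iterable[float]) -> float:
    """Geometric mean exp(mean(ln x)) of positive values."""
    return float(np.exp(np.mean(np.log(_as_positive_array(values)))))


def geocv_pct(values: Iterable[float]) -> float:
    """Geometric coefficient of variation, in percent.

    Uses the n-1 sample variance of the log values; requires n >= 2.
    """
    arr = _as_positive_array(values)
    if arr.size < 2:
        raise ValueError("geocv_pct requires at least two values")
    s2 = float(np.var(np.log(arr), ddof=1))
    return 100.0 * math.sqrt(math.expm1(s2))


def median_range(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, min, max); the even-n median averages the two central values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def summary_cell(values: Sequence[float], n_total: int) -> SummaryCell:
    """Summarise one parameter across a cohort of ``n_total`` subjects.

    ``values`` holds the properly determined entries (one per contributing
    subject).  GeoMean/GeoCV are suppressed when fewer than two thirds of
    the cohort contributed; GeoCV additionally needs n >= 2.
    """
    n_used = len(values)
    valid = n_used >= math.ceil(2.0 / 3.0 * n_total) and n_used > 0
    if not valid:
        return SummaryCell(n_used=n_used, n_total=n_total, valid=False,
                           geomean=None, geocv_pct=None, median=None,
                           range_lo=None, range_hi=None)
    med, lo, hi = median_range(values)
    return SummaryCell(
        n_used=n_used, n_total=n_total, valid=True,
        geomean=geomean(values),
        geocv_pct=geocv_pct(values) if n_used >= 2 else None,
        median=med, range_lo=lo, range_hi=hi)


def _window_of(t_rel: float, windows: Sequence[SamplingWindow]) -> SamplingWindow | None:
    """Closed-left windows; the right edge is included when no adjacent
    window starts there (printed windows like 0.5-1 h are non-contiguous)."""
    los = {w.lo for w in windows}
    for w in windows:
        if w.lo <= t_rel < w.hi:
            return w
        if t_rel == w.hi and w.hi not in los:
            return w
    return None


def bin_concentrations(subjects: Sequence[SubjectRecord],
                       windows: Sequence[SamplingWindow]) -> dict[str, SummaryCell]:
    """Per-window concentration summaries across subjects.

    Each quantifiable observation is assigned to the window containing its
    elapsed time since the start of the most recent prior infusion; at most
    one observation per subject per window is kept (the first; later ties
    are logged).  Observations before the first dose are excluded with a
    log entry.
    """
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if a.lo < b.hi and b.lo < a.hi:
                raise ValueError(f"windows {a.label!r} and {b.label!r} overlap")
    per_window: dict[str, list[float]] = {w.label: [] for w in windows}
    for subj in subjects:
        inf_starts = sorted(e.start_time for e in subj.dosing
                            if e.route is Route.IV_INFUSION)
        taken: set[str] = set()
        for ob in sorted(subj.observations, key=lambda o: o.time):
            if ob.blq_flag:
                continue
            prior_starts = [s for s in inf_starts if s <= ob.time]
            if not prior_starts:
                logger.info("subject %s: observation at %.3f h precedes the "
                            "first infusion; excluded", subj.subject_id, ob.time)
                continue
            w = _window_of(ob.time - prior_starts[-1], windows)
            if w is None:
                continue
            if w.label in taken:
                logger.info("subject %s: extra observation at %.3f h in window "
                            "%s ignored (first kept)", subj.subject_id, ob.time,
                            w.label)
                continue
            taken.add(w.label)
            per_window[w.label].append(ob.value)
    return {label: summary_cell(vals, n_total=len(subjects))
            for label, vals in per_window.items()}
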