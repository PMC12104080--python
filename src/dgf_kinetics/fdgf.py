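"""Functional delayed-graft-function (fDGF) classification.

DGF is declared functionally — without reference to the dialysis indication —
when serum creatinine fails to fall spontaneously by at least 10% per day on
three consecutive days during the first post-transplant week, or when dialysis
is required in that week.  The second day of the first qualifying three-day
run is the *index day*: it dates the resolution of fDGF and defines its
duration, which is binned into four severity groups.

Conventions adopted here (the source definition leaves them open):

* Severity bins are half-open: ``[1, 7)`` no, ``[7, 14)`` mild, ``[14, 21)``
  moderate, ``[21, inf)`` severe.  The two published notations ("≥7–14" and
  "≥14–<21") are only mutually consistent as half-open intervals.
* "Spontaneously" is operationalized by the default spontaneity rule: a day
  does not qualify if dialysis took place on that day or the day before
  (a creatinine drop across a dialysis session is not spontaneous).  An
  ``ignore-dialysis`` rule is selectable for sensitivity analysis.
* A missing creatinine value breaks a run: three successive ≥10% declines
  cannot be asserted across an unobserved day.
* A patient who is fDGF-positive solely through the dialysis clause, but
  whose creatinine-derived index day falls before POD 7, is grouped as
  *mild* (the smallest fDGF-positive bin); ``duration_days`` keeps the
  creatinine-rule value and ``by_dialysis`` records why the patient is
  positive.  This corner is not covered by the functional definition itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .errors import IndeterminateSeverityError, SeriesError

__all__ = [
    "GROUPS",
    "SPONTANEITY_RULES",
    "CreatinineSeries",
    "FdgfResult",
    "daily_declines",
    "classify",
    "classify_cohort",
    "group_from_duration",
]

#: Severity groups in increasing order of fDGF duration.
GROUPS = ("no", "mild", "moderate", "severe")

#: Lower edges of the half-open duration bins, aligned with :data:`GROUPS`.
_BIN_EDGES = (1, 7, 14, 21)

SPONTANEITY_RULES = ("exclude-post-dialysis", "ignore")

#: Minimum relative daily decline for a qualifying day.
DECLINE_THRESHOLD = 0.10

#: A resolution run spans this many consecutive qualifying days.
RUN_LENGTH = 3


@dataclass(frozen=True)
class CreatinineSeries:
    """Daily serum creatinine for one patient.

    Parameters
    ----------
    pods
        Strictly increasing postoperative days, starting at 1.
    values
        Serum creatinine in µmol/L aligned with ``pods``; ``None``/NaN marks
        a missing measurement.  Present values must be positive.
    dialysis_days
        PODs on which a dialysis session took place.
    """

    pods: tuple[int, ...]
    values: tuple[float | None, ...]
    dialysis_days: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        pods = tuple(int(p) for p in self.pods)
        values = tuple(
            None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            for v in self.values
        )
        object.__setattr__(self, "pods", pods)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dialysis_days", frozenset(int(d) for d in self.dialysis_days))
        if len(pods) != len(values):
            raise SeriesError("pods and values must have equal length")
        if len(pods) < 2:
            raise SeriesError("a creatinine series needs at least two days")
        if any(b <= a for a, b in zip(pods, pods[1:])):
            raise SeriesError("pods must be strictly increasing")
        if pods[0] < 1:
            raise SeriesError("pods start at 1")
        if any(v is not None and v <= 0 for v in values):
            raise SeriesError("creatinine values must be positive")

    @property
    def last_pod(self) -> int:
        return self.pods[-1]

    def value_on(self, pod: int) -> float | None:
        """Creatinine on a calendar POD, ``None`` if unobserved."""
        try:
            return self.values[self.pods.index(pod)]
        except ValueError:
            return None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CreatinineSeries":
        """Build from a `creatinine.csv`-shaped frame for one patient."""
        df = df.sort_values("pod")
        dial = frozenset(df.loc[df["dialysis_flag"].astype(bool), "pod"].astype(int))
        return cls(
            pods=tuple(df["pod"].astype(int)),
            values=tuple(None if pd.isna(v) else float(v)
                         for v in df["serum_creatinine_umol_l"]),
            dialysis_days=dial,
        )


@dataclass(frozen=True)
class FdgfResult:
    """Outcome of the fDGF classifier for one patient."""

    present: bool
    by_dialysis: bool
    resolution_index_day: int | None
    duration_days: int
    censored: bool
    group: str
    daily_declines: pd.Series

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def daily_declines(series: CreatinineSeries) -> pd.Series:
    """Relative daily creatinine declines r_d = (C_{d-1} - C_d) / C_{d-1}.

    Returns a Series indexed by POD ``d`` from 2 to the last observed day.
    ``r_d`` is NaN when either day's value is unobserved (including calendar
    days absent from the series).
    """
    last = series.last_pod
    out = pd.Series(np.nan, index=pd.RangeIndex(2, last + 1, name="pod"), name="r_d")
    for d in out.index:
        prev, cur = series.value_on(d - 1), series.value_on(d)
        if prev is not None and cur is not None:
            out.loc[d] = (prev - cur) / prev
    return out


def group_from_duration(duration_days: float) -> str:
    """Map an fDGF duration (days) onto its half-open severity bin."""
    if duration_days < 1:
        raise ValueError("duration must be >= 1 day")
    for name, lo, hi in zip(GROUPS, _BIN_EDGES, _BIN_EDGES[1:] + (math.inf,)):
        if lo <= duration_days < hi:
            return name
    raise AssertionError("bins partition [1, inf)")  # pragma: no cover


def _qualifying_days(series: CreatinineSeries, spontaneity_rule: str,
                     declines: pd.Series) -> set[int]:
    if spontaneity_rule not in SPONTANEITY_RULES:
        raise ValueError(f"spontaneity_rule must be one of {SPONTANEITY_RULES}")
    qualifying = set()
    for d, r in declines.items():
        if np.isnan(r) or r < DECLINE_THRESHOLD:
            continue
        if spontaneity_rule == "exclude-post-dialysis" and (
            d in series.dialysis_days or (d - 1) in series.dialysis_days
        ):
            continue
        qualifying.add(d)
    return qualifying


def _first_run_index(qualifying: set[int], last_day: int) -> int | None:
    """Index day (second day) of the earliest 3-consecutive-day run."""
    for start in range(2, last_day - RUN_LENGTH + 2):
        if all(start + k in qualifying for k in range(RUN_LENGTH)):
            return start + 1
    return None


def classify(
    series: CreatinineSeries,
    spontaneity_rule: str = "exclude-post-dialysis",
    followup_end: int | None = None,
) -> FdgfResult:
    """Classify fDGF presence, resolution day, duration and severity.

    Parameters
    ----------
    series
        Daily creatinine with dialysis log; must cover PODs 1–7.
    spontaneity_rule
        ``"exclude-post-dialysis"`` (default) disqualifies declines on a
        dialysis day or the day after; ``"ignore"`` uses raw declines.
    followup_end
        Last POD considered (default: last observed day).  Must be ≥ 7; if
        < 21 and no resolution run is found the severity is indeterminate
        and an error is raised rather than a silently wrong group.
    """
    if followup_end is None:
        followup_end = series.last_pod
    if followup_end < 7:
        raise SeriesError("followup_end must be >= 7 to determine fDGF presence")
    if series.pods[0] > 1 or series.last_pod < 7:
        raise SeriesError("series must cover PODs 1-7 for presence determination")

    declines = daily_declines(series)
    declines = declines.loc[declines.index <= followup_end]
    qualifying = _qualifying_days(series, spontaneity_rule, declines)
    index_day = _first_run_index(qualifying, min(series.last_pod, followup_end))

    by_dialysis = any(1 <= d <= 7 for d in series.dialysis_days)
    present = (index_day is None or index_day >= 7) or by_dialysis

    if index_day is not None:
        duration, censored = index_day, False
    else:
        duration, censored = followup_end, True

    if censored:
        if followup_end < 21:
            raise IndeterminateSeverityError(
                f"no resolution run by POD {followup_end} (< 21): "
                "cannot distinguish moderate from severe fDGF"
            )
        group = "severe"
    else:
        group = group_from_duration(duration)
        if present and group == "no":
            # positive via the dialysis clause only; floor into the mild bin
            group = "mild"

    return FdgfResult(
        present=present,
        by_dialysis=by_dialysis,
        resolution_index_day=index_day,
        duration_days=duration,
        censored=censored,
        group=group,
        daily_declines=declines,
    )


def classify_cohort(
    creatinine: pd.DataFrame,
    spontaneity_rule: str = "exclude-post-dialysis",
    followup_end: int | None = None,
) -> pd.DataFrame:
    """Classify every patient in a long-format creatinine table.

    ``creatinine`` has columns patient_id, pod, serum_creatinine_umol_l,
    dialysis_flag (the `creatinine.csv` contract).  Returns one row per
    patient: present, by_dialysis, index_day, duration, censored, group.
    """
    rows = []
    for pid, sub in creatinine.groupby("patient_id", sort=True):
        res = classify(CreatinineSeries.from_frame(sub), spontaneity_rule, followup_end)
        rows.append({
            "patient_id": pid,
            "present": res.present,
            "by_dialysis": res.by_dialysis,
            "index_day": res.resolution_index_day,
            "duration_days": res.duration_days,
            "censored": res.censored,
            "group": res.group,
        })
    return pd.DataFrame(rows)
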