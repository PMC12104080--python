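"""fDGF classifier: run detection, index day, severity bins, spontaneity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dgf_kinetics import CreatinineSeries, classify, daily_declines
from dgf_kinetics.errors import IndeterminateSeverityError, SeriesError
from dgf_kinetics.fdgf import GROUPS, classify_cohort, group_from_duration


# ---------------------------------------------------------------------------
# independent oracle: exhaustive run detection on a qualifying-day pattern
# ---------------------------------------------------------------------------

def brute_force_fdgf(qualifying: dict[int, bool], followup_end: int):
    """Scan every day for the first 3-consecutive-qualifying-day run."""
    index_day = None
    for start in range(2, followup_end + 1):
        if all(qualifying.get(start + k, False) for k in (0, 1, 2)) \
                and start + 2 <= followup_end:
            index_day = start + 1
            break
    present = index_day is None or index_day >= 7
    if index_day is None:
        if followup_end < 21:
            return present, None, None  # severity indeterminate
        return present, None, "severe"
    if index_day < 7:
        group = "no"
    elif index_day < 14:
        group = "mild"
    elif index_day < 21:
        group = "moderate"
    else:
        group = "severe"
    return present, index_day, group


def series_from_pattern(pattern: tuple[bool, ...], start: float = 1000.0,
                        dialysis=()) -> CreatinineSeries:
    """Creatinine series whose day-d decline qualifies iff pattern[d-2]."""
    values = [start]
    for q in pattern:
        values.append(values[-1] * (0.80 if q else 0.95))
    return CreatinineSeries(
        pods=tuple(range(1, len(values) + 1)),
        values=tuple(values),
        dialysis_days=frozenset(dialysis),
    )


def test_exhaustive_patterns_14_days_match_brute_force():
    """All 2^13 qualifying patterns over a 14-day window agree with the oracle."""
    n_days = 14
    for bits in range(2 ** (n_days - 1)):
        pattern = tuple(bool(bits >> k & 1) for k in range(n_days - 1))
        series = series_from_pattern(pattern)
        present_o, index_o, group_o = brute_force_fdgf(
            {d: q for d, q in enumerate(pattern, start=2)}, n_days)
        if group_o is None:
            with pytest.raises(IndeterminateSeverityError):
                classify(series)
            continue
        res = classify(series)
        assert res.present == present_o
        assert res.resolution_index_day == index_o
        assert res.group == group_o


def test_daily_declines_arithmetic_and_missing_propagation():
    s = CreatinineSeries(pods=(1, 2), values=(500.0, 450.0))
    assert daily_declines(s).loc[2] == pytest.approx(0.10)
    s = CreatinineSeries(pods=(1, 2), values=(500.0, 500.0))
    assert daily_declines(s).loc[2] == 0.0
    s = CreatinineSeries(pods=(1, 2, 3), values=(400.0, None, 300.0))
    r = daily_declines(s)
    assert np.isnan(r.loc[2]) and np.isnan(r.loc[3])
    with pytest.raises(SeriesError):
        CreatinineSeries(pods=(1,), values=(400.0,))


def test_prompt_recovery_is_no_fdgf():
    """15%/day decline from POD 1: run on days 2-4, index day 3, no fDGF."""
    values = tuple(800.0 * 0.85 ** d for d in range(7))
    s = CreatinineSeries(pods=tuple(range(1, 8)), values=values)
    res = classify(s)
    assert not res.present
    assert res.resolution_index_day == 3
    assert res.duration_days == 3
    assert res.group == "no"


def test_late_recovery_is_severe():
    """Flat creatinine through POD 20, then 15%/day: index day 22, severe."""
    flat = [700.0] * 20
    declining = [flat[-1] * 0.85 ** k for k in range(1, 9)]
    s = CreatinineSeries(pods=tuple(range(1, 29)), values=tuple(flat + declining))
    # oracle: first qualifying day is 21, so first run is 21-23, index 22
    res = classify(s)
    assert res.present
    assert res.resolution_index_day == 22
    assert res.group == "severe"


def test_dialysis_clause_forces_presence():
    """Prompt decline but dialysis on POD 3: present via the dialysis clause."""
    values = tuple(800.0 * 0.85 ** d for d in range(8))
    s = CreatinineSeries(pods=tuple(range(1, 9)), values=values,
                         dialysis_days=frozenset({3}))
    res = classify(s)
    assert res.present and res.by_dialysis
    # default spontaneity rule: days 3 and 4 no longer qualify, so the first
    # run is 5-6-7 and the index day moves to 6
    assert res.resolution_index_day == 6
    res_ignore = classify(s, spontaneity_rule="ignore")
    assert res_ignore.resolution_index_day == 3
    assert res_ignore.present  # still positive through the dialysis clause
    assert res_ignore.group == "mild"  # dialysis-only positive, duration < 7


def test_missing_day_breaks_a_run():
    values = [1000.0]
    for q in (True, True, True, False, False, False):
        values.append(values[-1] * (0.8 if q else 0.95))
    s_full = CreatinineSeries(pods=tuple(range(1, 8)), values=tuple(values))
    assert classify(s_full).resolution_index_day == 3
    gap = list(values)
    gap[2] = None  # unobserved POD 3 interrupts days 3 and 4
    s_gap = CreatinineSeries(pods=tuple(range(1, 8)), values=tuple(gap))
    with pytest.raises(IndeterminateSeverityError):
        classify(s_gap)


def test_short_followup_errors():
    values = tuple(700.0 for _ in range(14))
    s = CreatinineSeries(pods=tuple(range(1, 15)), values=values)
    with pytest.raises(SeriesError):
        classify(s, followup_end=6)
    with pytest.raises(IndeterminateSeverityError):
        classify(s, followup_end=14)


@given(st.integers(1, 60))
def test_duration_bins_partition(duration):
    group = group_from_duration(duration)
    lo, hi = {"no": (1, 7), "mild": (7, 14), "moderate": (14, 21),
              "severe": (21, math.inf)}[group]
    assert lo <= duration < hi


@given(
    st.lists(st.booleans(), min_size=13, max_size=27),
    st.floats(0.1, 1e6),
)
def test_scale_invariance(pattern, scale):
    """Multiplying the whole series by a constant never changes the result."""
    pattern = tuple(pattern)
    s1 = series_from_pattern(pattern, start=1000.0)
    s2 = series_from_pattern(pattern, start=1000.0 * scale)
    followup = len(pattern) + 1
    try:
        r1 = classify(s1, followup_end=followup)
    except IndeterminateSeverityError:
        with pytest.raises(IndeterminateSeverityError):
            classify(s2, followup_end=followup)
        return
    r2 = classify(s2, followup_end=followup)
    assert (r1.present, r1.resolution_index_day, r1.group) == \
        (r2.present, r2.resolution_index_day, r2.group)


@given(st.lists(st.booleans(), min_size=27, max_size=27), st.integers(0, 26))
def test_monotonicity_extra_qualifying_day_never_lengthens(pattern, flip):
    """Making one more day qualifying can never increase the duration."""
    base = tuple(pattern)
    more = tuple(q or (i == flip) for i, q in enumerate(base))
    d_base = classify(series_from_pattern(base)).duration_days
    d_more = classify(series_from_pattern(more)).duration_days
    assert d_more <= d_base


def test_classify_cohort_frame_round_trip():
    df = pd.DataFrame({
        "patient_id": ["a"] * 7 + ["b"] * 28,
        "pod": list(range(1, 8)) + list(range(1, 29)),
        "serum_creatinine_umol_l": [800 * 0.85 ** d for d in range(7)]
        + [700.0] * 28,
        "dialysis_flag": 0,
    })
    out = classify_cohort(df).set_index("patient_id")
    assert out.loc["a", "group"] == "no"
    assert out.loc["b", "group"] == "severe" and out.loc["b", "censored"]
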