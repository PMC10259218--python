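"""Trajectory classification against an independent rule oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcdmi.models import LabResult, TrajectoryGroup
from pcdmi.trajectory import (
    AbnormalitySeries,
    classify_series,
    classify_short_followup,
    flag_abnormal,
    trajectory_points,
)

PN = TrajectoryGroup.PERSISTENTLY_NORMAL
NM = TrajectoryGroup.NORMALIZED
RR = TrajectoryGroup.RELAPSING_REMITTING


def rule_oracle(obs, followup, window=1.0):
    """Direct brute-force restatement of the three verbal grouping rules."""
    flags = [a for _, a in obs]
    if followup < window:
        if flags[-1]:
            return RR  # ongoing inflammation at last observation
        return NM if any(flags) else PN
    if not any(flags):
        return PN
    normalized = True
    if any(a and t > window for t, a in obs):
        normalized = False  # abnormal beyond the window
    for i in range(len(obs)):
        if obs[i][1] and any(not obs[j][1] for j in range(i)):
            normalized = False  # recurrence after a normal result
    return NM if normalized else RR


def make_series(times, flags, followup):
    return AbnormalitySeries(
        patient_id="p", analyte="crp",
        observations=tuple(zip(times, flags)), followup_years=followup,
    )


# ---------------------------------------------------------------------------
# abnormality flagging
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,lo,hi,expected",
    [
        (80.0, 110.0, 140.0, True),     # below a two-sided range
        (110.0, 110.0, 140.0, False),   # exactly at a bound is normal
        (140.0, 110.0, 140.0, False),
        (125.0, 110.0, 140.0, False),
        (900.0, None, 50.0, True),      # one-sided upper (calprotectin)
        (30.0, None, 50.0, False),
        (20.0, 35.0, None, True),       # one-sided lower
    ],
)
def test_flag_abnormal(value, lo, hi, expected):
    r = LabResult(patient_id="p", analyte="x", t_years=0.0,
                  value=value, ref_low=lo, ref_high=hi)
    assert flag_abnormal(r) is expected


def test_flag_abnormal_requires_reference_range():
    r = LabResult(patient_id="p", analyte="x", t_years=0.0, value=5.0)
    with pytest.raises(ValueError, match="reference range"):
        flag_abnormal(r)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "times,flags,followup,expected",
    [
        # persistently normal whatever the times
        ([0.0, 1.0, 4.0], [False, False, False], 5.0, PN),
        # initially abnormal, normalises within the window, stays normal
        ([0.0, 0.4, 0.9, 2.1, 3.5], [True, True, False, False, False], 4.0, NM),
        # relapse after the window
        ([0.0, 1.5, 3.0], [True, False, True], 4.0, RR),
        # oscillation entirely inside the window counts as relapsing
        ([0.0, 0.3, 0.6, 2.0], [True, False, True, False], 3.0, RR),
        # all abnormal confined to the window, no normal tail observation yet
        ([0.1, 0.2], [True, True], 2.0, NM),
    ],
)
def test_classify_series_examples(times, flags, followup, expected):
    assert classify_series(make_series(times, flags, followup)) is expected


@pytest.mark.parametrize(
    "times,flags,followup,expected",
    [
        ([0.0, 0.5], [True, False], 0.6, NM),    # normalised by last result
        ([0.0, 0.5], [True, True], 0.6, RR),     # ongoing inflammation
        ([0.2], [False], 0.6, PN),
    ],
)
def test_short_followup_rule(times, flags, followup, expected):
    series = make_series(times, flags, followup)
    assert classify_short_followup(series) is expected
    assert classify_series(series) is expected  # dispatched automatically


def test_empty_series_rejected():
    with pytest.raises(ValueError, match="empty series"):
        classify_series(make_series([], [], 2.0))


def test_exhaustive_oracle_equivalence():
    """Classifier agrees with the brute-force oracle on every abnormality
    sequence of length <= 6 on a fixed time grid spanning the window."""
    grid = [0.0, 0.3, 0.8, 1.4, 2.5, 3.6]
    followup = 4.0
    checked = 0
    for n in range(1, 7):
        times = grid[:n]
        for flags in itertools.product([False, True], repeat=n):
            series = make_series(times, flags, followup)
            obs = list(zip(times, flags))
            assert classify_series(series) is rule_oracle(obs, followup), (times, flags)
            checked += 1
    assert checked == 126


def test_exhaustive_oracle_equivalence_short_followup():
    grid = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    followup = 0.6
    for n in range(1, 7):
        times = grid[:n]
        for flags in itertools.product([False, True], repeat=n):
            series = make_series(times, flags, followup)
            obs = list(zip(times, flags))
            assert classify_series(series) is rule_oracle(obs, followup)


@given(
    flags=st.lists(st.booleans(), min_size=1, max_size=8),
    extra_norm=st.floats(min_value=1.1, max_value=9.0),
)
@settings(max_examples=200, deadline=None)
def test_permanence_properties(flags, extra_norm):
    """Appending a normal result never demotes NORMALIZED to relapsing;
    appending a post-window abnormal result always yields relapsing."""
    times = [i * 0.1 for i in range(len(flags))]
    followup = 10.0
    base = classify_series(make_series(times, flags, followup))

    with_normal = make_series(times + [extra_norm], list(flags) + [False], followup)
    if base is NM:
        assert classify_series(with_normal) is NM

    with_abnormal = make_series(times + [extra_norm], list(flags) + [True], followup)
    assert classify_series(with_abnormal) is RR


@given(flags=st.lists(st.booleans(), min_size=1, max_size=8))
@settings(max_examples=100, deadline=None)
def test_abnormal_at_diagnosis_never_persistently_normal(flags):
    """A series abnormal at t=0 (every calprotectin series at diagnosis)
    can never classify as persistently normal."""
    times = [i * 0.5 for i in range(1 + len(flags))]
    series = make_series(times, [True] + list(flags), followup=6.0)
    assert classify_series(series) is not PN


# ---------------------------------------------------------------------------
# points mapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("group,points", [(PN, 0), (NM, 1), (RR, 3)])
def test_trajectory_points(group, points):
    assert trajectory_points(group) == points


def test_insufficient_data_is_not_scoreable():
    with pytest.raises(ValueError, match="missing component"):
        trajectory_points(TrajectoryGroup.INSUFFICIENT_DATA)


def test_series_from_results_sorts_and_flags():
    rows = [
        LabResult(patient_id="p", analyte="crp", t_years=2.0, value=40.0, ref_high=5.0),
        LabResult(patient_id="p", analyte="crp", t_years=0.0, value=3.0, ref_high=5.0),
    ]
    series = AbnormalitySeries.from_results(rows, followup_years=3.0)
    assert series.observations == ((0.0, False), (2.0, True))
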