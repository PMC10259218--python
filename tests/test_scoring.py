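"""Component scoring, growth flags, coefficients, and their derivation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcdmi.config import CoefficientBand, ScoreConfig
from pcdmi.models import GrowthMeasure, PatientSummary, TrajectoryGroup
from pcdmi.scoring import (
    assess_growth,
    component_points,
    compute_pcdmi,
    derive_coefficients,
    followup_coefficient,
)
from pcdmi.synthetic_cohort import maximal_patient_summary, quiescent_patient_summary

RR = TrajectoryGroup.RELAPSING_REMITTING


def growth(*sds, dim="weight"):
    return [
        GrowthMeasure(patient_id="p", dimension=dim, t_years=i * 1.0, sds=s)
        for i, s in enumerate(sds)
    ]


# ---------------------------------------------------------------------------
# growth flags
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "series,triggered,reason",
    [
        (growth(-0.5, -1.8), True, "fall_gt_1sd"),          # fall of 1.3 SDS
        (growth(-0.5, -1.4), False, "none"),                 # fall of 0.9 only
        (growth(-0.5, -1.5), False, "none"),                 # fall of exactly 1.0
        (growth(-1.5, -1.6, -2.3), True, "dropped_below_minus2"),
        (growth(-2.4, -1.1), False, "none"),                 # improvement exemption
        (growth(-2.4, -2.5), True, "no_improvement_from_below_minus2"),
        (growth(-1.0), False, "none"),                       # single measure
        (growth(-2.6), True, "no_improvement_from_below_minus2"),
    ],
)
def test_assess_growth(series, triggered, reason):
    flag = assess_growth(series)
    assert flag.triggered is triggered
    assert flag.reason == reason


def test_assess_growth_uses_earliest_measure_as_baseline():
    series = [
        GrowthMeasure(patient_id="p", dimension="height", t_years=2.0, sds=-1.9),
        GrowthMeasure(patient_id="p", dimension="height", t_years=0.0, sds=-0.2),
    ]
    flag = assess_growth(series)  # baseline -0.2, later -1.9: fall of 1.7
    assert flag.triggered and flag.reason == "fall_gt_1sd"


def test_assess_growth_empty_is_missing_component():
    with pytest.raises(ValueError, match="missing"):
        assess_growth([])


# ---------------------------------------------------------------------------
# component points and the index
# ---------------------------------------------------------------------------

def test_all_quiescent_patient_scores_zero():
    comps, missing = component_points(quiescent_patient_summary(4.0))
    assert sum(comps.values()) == 0.0
    assert missing == []


def test_maximal_standard_patient_scores_exactly_50():
    comps, missing = component_points(maximal_patient_summary(3.0))
    assert sum(comps.values()) == 50.0
    assert missing == []
    # domain subtotals
    assert sum(comps[a] for a in ("hemoglobin", "crp", "platelets", "albumin",
                                  "calprotectin")) == 15.0
    assert comps["second_line_monoclonal_or_small_molecule"] == 4.0
    assert comps["intestinal_resection"] == 4.0
    assert comps["liver"] == 3.0


def test_fifth_eim_category_pushes_base_above_50():
    comps, _ = component_points(maximal_patient_summary(3.0, include_other_autoimmune=True))
    assert sum(comps.values()) == 52.0 > 50.0


def test_medication_classes_are_additive():
    s = quiescent_patient_summary(4.0).model_copy(
        update={"meds": {k: True for k in (
            "asa_topical", "immunomodulator", "first_line_monoclonal",
            "second_line_monoclonal_or_small_molecule")}}
    )
    comps, _ = component_points(s)
    assert sum(comps.values()) == 1 + 2 + 3 + 4


def test_insufficient_lab_is_marked_missing_not_zero_scored_silently():
    s = quiescent_patient_summary(4.0)
    s.trajectory = dict(s.trajectory)
    s.trajectory["crp"] = TrajectoryGroup.INSUFFICIENT_DATA
    comps, missing = component_points(s)
    assert comps["crp"] == 0.0
    assert missing == ["crp"]


def test_unknown_component_key_is_configuration_error():
    s = quiescent_patient_summary(4.0)
    cfg = ScoreConfig()
    del cfg.weights["arthritis"]
    with pytest.raises(KeyError):
        component_points(s, cfg)


@pytest.mark.parametrize(
    "years,multiplier",
    [
        (0.5, 2.0), (0.99, 2.0),
        (1.0, 1.5), (2.75, 1.5),
        (3.0, 1.25),  # half-open bands: exactly 3.0 falls in the 3-5 band
        (4.99, 1.25),
        (5.0, 1.1), (9.5, 1.1),
        (10.0, 1.0), (12.0, 1.0), (40.0, 1.0),
    ],
)
def test_followup_coefficient_bands(years, multiplier):
    assert followup_coefficient(years) == multiplier


def test_followup_coefficient_rejects_nonpositive():
    with pytest.raises(ValueError):
        followup_coefficient(0.0)


def test_adjusted_score_worked_examples():
    assert compute_pcdmi(maximal_patient_summary(0.5)).adjusted_score == 100.0
    assert compute_pcdmi(maximal_patient_summary(2.75)).adjusted_score == 75.0
    assert compute_pcdmi(quiescent_patient_summary(7.0)).adjusted_score == 0.0


booleans = st.booleans()


@given(
    groups=st.lists(
        st.sampled_from([TrajectoryGroup.PERSISTENTLY_NORMAL,
                         TrajectoryGroup.NORMALIZED, RR]),
        min_size=5, max_size=5),
    bools=st.lists(booleans, min_size=15, max_size=15),
    followup=st.floats(min_value=0.1, max_value=30.0),
)
@settings(max_examples=150, deadline=None)
def test_additivity_and_bounds(groups, bools, followup):
    """base = sum(components); defaults give base in [0,52], adjusted <= 104,
    and adjusted <= 100 whenever the fifth EIM category is off."""
    analytes = ("hemoglobin", "crp", "platelets", "albumin", "calprotectin")
    meds = ("asa_topical", "immunomodulator", "first_line_monoclonal",
            "second_line_monoclonal_or_small_molecule")
    eims = ("liver", "skin", "eye", "arthritis", "other_autoimmune")
    it = iter(bools)
    s = PatientSummary(
        patient_id="p", followup_years=followup,
        trajectory=dict(zip(analytes, groups)),
        meds={k: next(it) for k in meds},
        complications={"stricturing": next(it), "fistulating": next(it)},
        surgery={"intestinal_resection": next(it), "perianal_procedure": next(it)},
        growth_flags={"weight_flag": next(it), "height_flag": next(it)},
        eims={k: next(it) for k in eims},
    )
    r = compute_pcdmi(s)
    assert r.base_score == pytest.approx(sum(r.components.values()))
    assert 0 <= r.base_score <= 52
    assert 0 <= r.adjusted_score <= 104
    if not s.eims["other_autoimmune"]:
        assert r.adjusted_score <= 100


# ---------------------------------------------------------------------------
# coefficient derivation
# ---------------------------------------------------------------------------

def test_equal_band_means_give_all_factors_one():
    scores = [10.0, 10.0, 10.0, 10.0, 10.0]
    years = [0.5, 2.0, 4.0, 7.0, 12.0]
    table = derive_coefficients(scores, years)
    assert [b.multiplier for b in table.bands] == [1.0] * 5
    assert table.provenance == "derived-from-cohort"


def test_hand_computed_three_band_cohort():
    """Band means {2.5, 5, 10} with edges at 1 and 10 years: the factor is
    overall_mean / band_mean rescaled to the longest band, i.e. the ratio of
    the longest band's mean to each band's mean -> {4.0, 2.0, 1.0}."""
    scores = [2.5, 2.5, 5.0, 5.0, 10.0, 10.0]
    years = [0.3, 0.7, 2.0, 8.0, 11.0, 14.0]
    table = derive_coefficients(scores, years, band_edges=(1.0, 10.0))
    assert [b.multiplier for b in table.bands] == [4.0, 2.0, 1.0]


def test_empty_short_band_extrapolated_by_linear_extension():
    """A cohort with no <1-year patients whose populated bands derive
    {1.5, 1.25, 1.1, 1.0} gets a <1-year factor above the 1-3-year one."""
    # choose band means inversely proportional to the target factors
    # (factor_i = mean_last / mean_i after rescaling)
    targets = {(1.0, 3.0): 1.5, (3.0, 5.0): 1.25, (5.0, 10.0): 1.1, (10.0, math.inf): 1.0}
    scores, years = [], []
    for (lo, hi), f in targets.items():
        mean = 12.0 / f
        scores += [mean - 1.0, mean + 1.0]
        years += [lo + 0.1, lo + 0.2]
    table = derive_coefficients(scores, years)
    multipliers = [b.multiplier for b in table.bands]
    assert multipliers[1:] == [1.5, 1.25, 1.1, 1.0]
    assert multipliers[0] >= 1.5  # extrapolated short-follow-up factor
    # linear extension of 1.5, 1.25 backwards gives 1.75
    assert multipliers[0] == pytest.approx(1.75)


def test_derived_table_monotone_for_increasing_band_means():
    scores = [4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0]
    years = [0.4, 0.8, 1.5, 2.5, 3.5, 4.5, 6.0, 9.0, 11.0, 13.0]
    table = derive_coefficients(scores, years)
    mults = [b.multiplier for b in table.bands]
    assert mults == sorted(mults, reverse=True)
    assert mults[-1] == 1.0


def test_derivation_errors():
    with pytest.raises(ValueError, match="empty"):
        derive_coefficients([], [])
    with pytest.raises(ValueError, match="positive"):
        derive_coefficients([0.0, 0.0], [1.0, 2.0])


def test_band_table_partitions_configuration():
    """Default bands tile [0, inf) without gap or overlap and a custom
    gapped table is rejected."""
    cfg = ScoreConfig()
    edges = [(b.lower, b.upper) for b in cfg.coefficient_bands]
    assert edges[0][0] == 0.0 and math.isinf(edges[-1][1])
    assert all(u == nl for (_, u), (nl, _) in zip(edges, edges[1:]))
    with pytest.raises(ValueError, match="partition"):
        ScoreConfig(coefficient_bands=[
            CoefficientBand(lower=0.0, upper=1.0, multiplier=2.0),
            CoefficientBand(lower=2.0, upper=math.inf, multiplier=1.0),
        ])
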