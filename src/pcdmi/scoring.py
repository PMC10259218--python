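"""PCD-MI score computation.

The index sums points across five disease-burden themes (see
:mod:`pcdmi.config` for the default weight table), then multiplies the
base score by a follow-up-duration coefficient so that high burden
accrued over a short follow-up is comparable with burden accrued over a
decade.  With the default weights the standard range is 0-50 base
(0-100 adjusted); a patient with a fifth extraintestinal manifestation
category can exceed 50.

This module also implements the data-driven derivation of the
coefficient table from a scored cohort: the mean score per follow-up
band, compared with the overall mean, gives the factor needed to
normalise scores for that duration, rescaled so the longest-follow-up
band has coefficient 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import CoefficientBand, ScoreConfig
from .models import (
    COMPLICATIONS,
    EIMS,
    GROWTH_FLAGS,
    MED_CLASSES,
    SURGERIES,
    GrowthMeasure,
    PatientSummary,
    PCDMIResult,
    TrajectoryGroup,
)
from .trajectory import trajectory_points


# ---------------------------------------------------------------------------
# growth flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFlag:
    """Growth-failure assessment for one patient-dimension.

    ``reason`` records the first rule satisfied, in assessment order:
    a fall of >1.0 SDS from baseline; dropping below -2.0 SDS during
    follow-up from a baseline at or above -2.0; or no improvement from a
    baseline already below -2.0.
    """

    patient_id: str
    dimension: str
    triggered: bool
    reason: str  # fall_gt_1sd | dropped_below_minus2 | no_improvement_from_below_minus2 | none

    def __post_init__(self) -> None:
        if self.triggered != (self.reason != "none"):
            raise ValueError("triggered must correspond to a non-none reason")


def assess_growth(measures: Sequence[GrowthMeasure]) -> GrowthFlag:
    """Assess growth failure from one patient's series for one dimension.

    Baseline is the earliest QC-passed measure at or after diagnosis.
    A patient whose baseline SDS is already below -2.0 is exempt from
    the absolute -2.0 threshold and is flagged only if the final SDS
    shows no improvement over baseline — the score accounts for children
    whose natural growth potential is lower.
    """
    if not measures:
        raise ValueError("no growth measures: component is missing, not zero")
    dims = {m.dimension for m in measures}
    if len(dims) != 1:
        raise ValueError(f"mixed dimensions in one series: {sorted(dims)}")
    pids = {m.patient_id for m in measures}
    if len(pids) != 1:
        raise ValueError("mixed patients in one series")

    ordered = sorted(measures, key=lambda m: m.t_years)
    baseline = ordered[0].sds
    followup = [m.sds for m in ordered[1:]]
    final = ordered[-1].sds
    pid, dim = ordered[0].patient_id, ordered[0].dimension

    if followup and min(followup) < baseline - 1.0:
        return GrowthFlag(pid, dim, True, "fall_gt_1sd")
    if baseline >= -2.0 and any(s < -2.0 for s in followup):
        return GrowthFlag(pid, dim, True, "dropped_below_minus2")
    if baseline < -2.0 and final <= baseline:
        return GrowthFlag(pid, dim, True, "no_improvement_from_below_minus2")
    return GrowthFlag(pid, dim, False, "none")


# ---------------------------------------------------------------------------
# component points and the index
# ---------------------------------------------------------------------------

def component_points(
    summary: PatientSummary,
    config: Optional[ScoreConfig] = None,
) -> tuple[dict[str, float], list[str]]:
    """Map a patient summary to its per-component point breakdown.

    Returns ``(components, missing)``.  Every component of the active
    configuration appears in ``components``; those that could not be
    assessed (a lab series marked INSUFFICIENT_DATA or absent, or a
    growth dimension with no measures, signalled by an absent key in
    ``growth_flags``) contribute 0 and are listed in ``missing`` so
    cohort summaries can report completeness.  Medication classes are
    additive: each class ever used scores its own weight.
    """
    config = config or ScoreConfig()
    weights = config.weights
    known = set(weights) | set(config.analytes)
    for group in (summary.meds, summary.complications, summary.surgery,
                  summary.growth_flags, summary.eims):
        unknown = set(group) - known
        if unknown:
            raise KeyError(f"no weight configured for component(s) {sorted(unknown)}")

    components: dict[str, float] = {}
    missing: list[str] = []

    for analyte in config.analytes:
        group = summary.trajectory.get(analyte, TrajectoryGroup.INSUFFICIENT_DATA)
        if group is TrajectoryGroup.INSUFFICIENT_DATA:
            components[analyte] = 0.0
            missing.append(analyte)
        else:
            components[analyte] = trajectory_points(group, config)

    for keys, values in (
        (MED_CLASSES, summary.meds),
        (COMPLICATIONS, summary.complications),
        (SURGERIES, summary.surgery),
        (EIMS, summary.eims),
    ):
        for key in keys:
            components[key] = weights[key] if values.get(key, False) else 0.0

    for key in GROWTH_FLAGS:
        if key not in summary.growth_flags:
            components[key] = 0.0
            missing.append(key)
        else:
            components[key] = weights[key] if summary.growth_flags[key] else 0.0

    return components, missing


def followup_coefficient(
    followup_years: float,
    bands: Optional[Sequence[CoefficientBand]] = None,
) -> float:
    """Multiplier of the unique half-open band containing ``followup_years``."""
    if followup_years <= 0:
        raise ValueError("follow-up duration must be positive")
    if bands is None:
        bands = ScoreConfig().coefficient_bands
    for band in bands:
        if band.lower <= followup_years < band.upper:
            return band.multiplier
    raise ValueError(f"no coefficient band contains {followup_years} years")


def compute_pcdmi(
    summary: PatientSummary,
    config: Optional[ScoreConfig] = None,
) -> PCDMIResult:
    """Compute the full PCD-MI result for one patient.

    ``adjusted_score`` is kept at full precision; round to one decimal
    only on output.
    """
    config = config or ScoreConfig()
    components, missing = component_points(summary, config)
    base = float(sum(components.values()))
    coeff = followup_coefficient(summary.followup_years, config.coefficient_bands)
    return PCDMIResult(
        patient_id=summary.patient_id,
        components=components,
        missing=missing,
        base_score=base,
        coefficient=coeff,
        adjusted_score=base * coeff,
        followup_years=summary.followup_years,
    )


# ---------------------------------------------------------------------------
# data-driven coefficient derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientBandTable:
    bands: tuple[CoefficientBand, ...]
    provenance: str = "default"  # default | derived-from-cohort
    raw_ratios: tuple[float, ...] = ()


def derive_coefficients(
    base_scores: Sequence[float],
    followup_years: Sequence[float],
    band_edges: Sequence[float] = (1.0, 3.0, 5.0, 10.0),
) -> CoefficientBandTable:
    """Derive follow-up coefficients from a scored cohort.

    For each band the mean base score is compared with the overall mean
    score; the ratio ``overall_mean / band_mean`` is the factor needed to
    normalise scores accrued over that duration.  Factors are rescaled so
    the longest-follow-up band equals 1.0 and rounded to two decimals.
    Bands containing no patients are extrapolated by linear extension of
    the nearest derived factors (a cohort with no short-follow-up
    patients still needs a short-follow-up coefficient).
    """
    scores = np.asarray(base_scores, dtype=float)
    years = np.asarray(followup_years, dtype=float)
    if scores.size == 0:
        raise ValueError("empty cohort")
    if scores.size != years.size:
        raise ValueError("scores and follow-up durations must align")
    overall_mean = scores.mean()
    if overall_mean <= 0:
        raise ValueError("overall mean score must be positive to derive factors")

    edges = [0.0, *band_edges, math.inf]
    raw: list[Optional[float]] = []
    for lo, hi in zip(edges, edges[1:]):
        mask = (years >= lo) & (years < hi)
        if not mask.any():
            raw.append(None)
            continue
        band_mean = scores[mask].mean()
        if band_mean <= 0:
            raise ValueError(f"band [{lo}, {hi}) has mean score 0; cannot normalise")
        raw.append(overall_mean / band_mean)

    filled = _fill_by_linear_extension(raw)
    if filled[-1] <= 0:
        raise ValueError("longest-follow-up factor must be positive")
    rescaled = [f / filled[-1] for f in filled]

    bands = tuple(
        CoefficientBand(lower=lo, upper=hi, multiplier=round(m, 2))
        for (lo, hi), m in zip(zip(edges, edges[1:]), rescaled)
    )
    return CoefficientBandTable(
        bands=bands,
        provenance="derived-from-cohort",
        raw_ratios=tuple(float("nan") if r is None else r for r in raw),
    )


def _fill_by_linear_extension(raw: Sequence[Optional[float]]) -> list[float]:
    """Fill empty bands by linear extension on the band index.

    Interior gaps interpolate between neighbours; leading/trailing gaps
    extend the slope of the two nearest derived factors (or copy a lone
    factor).  Requires at least two non-empty bands unless only one band
    exists at all.
    """
    known = [(i, v) for i, v in enumerate(raw) if v is not None]
    if not known:
        raise ValueError("no band contains any data")
    if len(known) == 1:
        return [known[0][1]] * len(raw)
    if len(known) < 2 and any(v is None for v in raw):
        raise ValueError("need at least two populated bands to extrapolate")
    xs = np.array([i for i, _ in known], dtype=float)
    ys = np.array([v for _, v in known], dtype=float)
    out: list[float] = []
    for i, v in enumerate(raw):
        if v is not None:
            out.append(v)
        elif i < xs[0]:  # extend slope of the first two known factors
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out.append(float(ys[0] + slope * (i - xs[0])))
        elif i > xs[-1]:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out.append(float(ys[-1] + slope * (i - xs[-1])))
        else:  # interior gap
            out.append(float(np.interp(i, xs, ys)))
    return out


__all__ = [
    "GrowthFlag",
    "CoefficientBandTable",
    "assess_growth",
    "component_points",
    "followup_coefficient",
    "compute_pcdmi",
    "derive_coefficients",
]
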