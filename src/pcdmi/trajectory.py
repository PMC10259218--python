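"""Three-group classification of longitudinal abnormality series.

Each QC-passed patient-analyte series is reduced to a sequence of
abnormality flags (value outside the row's own reference interval) and
classified into one of three disease-activity groups:

* **persistently normal** — every result normal, including at diagnosis;
* **normalized** — initially abnormal, with all abnormal results inside
  the normalisation window (default 1 year after diagnosis) and normal
  results only thereafter;
* **relapsing-remitting** — any abnormal result after the window, or any
  recurrence of abnormality after a normal result.

A normal-to-abnormal recurrence *inside* the window is classified as
relapsing-remitting: oscillation is not "normalisation by one year".
This convention is configurable only through the window width; the
recurrence rule itself is fixed.

Series from patients with less than one window of follow-up cannot show
post-window behaviour, so a simpler end-state rule applies: normalized if
the last result is normal after at least one abnormal, relapsing-remitting
if inflammation is ongoing at the last result, persistently normal
otherwise.

The group maps to points 0 (persistently normal), 1 (normalized), 3
(relapsing-remitting) per analyte.  Scores are bound to these semantic
labels, never to group ordinals, which are numbered inconsistently in
common usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .config import ScoreConfig
from .models import LabResult, TrajectoryGroup


def flag_abnormal(result: LabResult) -> bool:
    """True iff the value lies outside the row's reference interval.

    The interval is inclusive: a value exactly at a bound is normal
    (standard laboratory flag convention).  One-sided ranges use the
    bound that is present.  Rows with no reference range cannot be
    flagged and must be excluded upstream.
    """
    if result.value is None:
        raise ValueError("cannot flag a result with no value; QC must run first")
    if not result.has_reference_range():
        raise ValueError(
            f"no reference range for {result.patient_id}/{result.analyte}; "
            "row should have been excluded from abnormality classification"
        )
    if result.ref_low is not None and result.value < result.ref_low:
        return True
    if result.ref_high is not None and result.value > result.ref_high:
        return True
    return False


@dataclass(frozen=True)
class AbnormalitySeries:
    """Ordered abnormality flags for one patient-analyte series."""

    patient_id: str
    analyte: str
    observations: tuple[tuple[float, bool], ...]  # (t_years, abnormal)
    followup_years: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.observations]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must be non-decreasing")

    @classmethod
    def from_results(
        cls,
        results: Sequence[LabResult],
        followup_years: float,
    ) -> "AbnormalitySeries":
        rows = sorted(
            (r for r in results if r.has_reference_range()),
            key=lambda r: r.t_years,
        )
        if not rows:
            raise ValueError("no classifiable rows (all lacked reference ranges?)")
        return cls(
            patient_id=rows[0].patient_id,
            analyte=rows[0].analyte,
            observations=tuple((r.t_years, flag_abnormal(r)) for r in rows),
            followup_years=followup_years,
        )


def classify_short_followup(series: AbnormalitySeries) -> TrajectoryGroup:
    """End-state rule for follow-up shorter than the normalisation window."""
    if not series.observations:
        raise ValueError("empty series: run QC and the observation-count rule first")
    flags = [abn for _, abn in series.observations]
    if flags[-1]:
        return TrajectoryGroup.RELAPSING_REMITTING  # ongoing inflammation
    if any(flags):
        return TrajectoryGroup.NORMALIZED
    return TrajectoryGroup.PERSISTENTLY_NORMAL


def classify_series(
    series: AbnormalitySeries,
    window_years: Optional[float] = None,
    config: Optional[ScoreConfig] = None,
) -> TrajectoryGroup:
    """Classify one abnormality series into its disease-activity group."""
    if not series.observations:
        raise ValueError("empty series: run QC and the observation-count rule first")
    if window_years is None:
        window_years = (config or ScoreConfig()).normalization_window_years

    if series.followup_years < window_years:
        return classify_short_followup(series)

    flags = [abn for _, abn in series.observations]
    if not any(flags):
        return TrajectoryGroup.PERSISTENTLY_NORMAL
    # abnormal beyond the window: never normalised
    if any(abn and t > window_years for t, abn in series.observations):
        return TrajectoryGroup.RELAPSING_REMITTING
    # recurrence: abnormal after any normal result (oscillation within the
    # window counts as relapsing, see module docstring)
    seen_normal = False
    for _, abn in series.observations:
        if abn and seen_normal:
            return TrajectoryGroup.RELAPSING_REMITTING
        if not abn:
            seen_normal = True
    return TrajectoryGroup.NORMALIZED


def trajectory_points(
    group: TrajectoryGroup, config: Optional[ScoreConfig] = None
) -> float:
    """Points awarded for one analyte's trajectory group (default 0/1/3)."""
    if group is TrajectoryGroup.INSUFFICIENT_DATA:
        raise ValueError(
            "INSUFFICIENT_DATA is a missing component, not a scoreable group"
        )
    points = (config or ScoreConfig()).trajectory_points
    return points[group]


def classify_cohort(
    series_map: dict[tuple[str, str], Sequence[LabResult]],
    followup: dict[str, float],
    config: Optional[ScoreConfig] = None,
) -> dict[tuple[str, str], TrajectoryGroup]:
    """Classify every (patient, analyte) series in a cohort."""
    config = config or ScoreConfig()
    out: dict[tuple[str, str], TrajectoryGroup] = {}
    for (pid, analyte), rows in series_map.items():
        abn = AbnormalitySeries.from_results(rows, followup_years=followup[pid])
        out[(pid, analyte)] = classify_series(
            abn, window_years=config.normalization_window_years
        )
    return out


__all__ = [
    "AbnormalitySeries",
    "flag_abnormal",
    "classify_series",
    "classify_short_followup",
    "trajectory_points",
    "classify_cohort",
]
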