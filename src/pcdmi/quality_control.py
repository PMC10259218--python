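"""Quality control of laboratory and growth data.

Three filters run before any trajectory classification or scoring:

* laboratory rows carrying an exclusion QC flag (hemolyzed, insufficient
  sample, failed test, sample not received, clotted) or a value outside
  per-analyte physiological plausibility bounds are rejected;
* growth SDS measurements outside plausibility bounds are rejected;
* per-patient-per-analyte series with fewer than ``min_n`` observations
  (default 5) are marked ``INSUFFICIENT_DATA`` for the blood analytes.
  Fecal calprotectin is exempt: stool sampling is sparse in routine care
  and any abnormal result since diagnosis still informs the trajectory,
  so calprotectin series of any length are classified.

Every filter is conserving (kept + rejected = input, order preserved
within the kept stream) and each rejection carries exactly one primary
reason — the first rule that fired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .config import ScoreConfig
from .models import EXCLUSION_QC_FLAGS, GrowthMeasure, LabResult, TrajectoryGroup

logger = logging.getLogger(__name__)

# Stable rejection-reason precedence: explicit sample-handling flags win
# over the implausibility check.
_FLAG_ORDER = (
    "hemolyzed",
    "insufficient_sample",
    "failed_test",
    "sample_not_received",
    "clotted",
    "implausible",
)


@dataclass
class QCReport:
    """Outcome of one filtering pass."""

    kept: list = field(default_factory=list)
    rejected: list[tuple[object, str]] = field(default_factory=list)
    counts_before: dict[str, int] = field(default_factory=dict)
    counts_after: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def _rejection_reason(
    result: LabResult, bounds: Optional[tuple[float, float]]
) -> Optional[str]:
    for flag in _FLAG_ORDER:
        if flag in result.qc_flags:
            return flag
    if result.value is None:
        return "missing_value"
    if bounds is not None:
        lo, hi = bounds
        if not lo <= result.value <= hi:
            return "implausible"
    return None


def filter_lab_results(
    results: Sequence[LabResult],
    plausibility: Optional[Mapping[str, tuple[float, float]]] = None,
    config: Optional[ScoreConfig] = None,
) -> QCReport:
    """Apply the exclusion-flag and plausibility filters to lab rows.

    Raises ``KeyError`` if an analyte appears for which no plausibility
    bounds are configured — unknown analytes must be registered, not
    silently passed through.
    """
    config = config or ScoreConfig()
    bounds_map = dict(config.plausibility_bounds)
    if plausibility is not None:
        bounds_map.update(plausibility)

    report = QCReport()
    for r in results:
        if r.analyte not in bounds_map:
            raise KeyError(
                f"no plausibility bounds configured for analyte {r.analyte!r}"
            )
        report.counts_before[r.analyte] = report.counts_before.get(r.analyte, 0) + 1
        reason = _rejection_reason(r, bounds_map[r.analyte])
        if reason is None:
            report.kept.append(r)
            report.counts_after[r.analyte] = report.counts_after.get(r.analyte, 0) + 1
        else:
            report.rejected.append((r, reason))
    return report


def filter_growth_measures(
    measures: Sequence[GrowthMeasure],
    sds_bounds: Optional[tuple[float, float]] = None,
) -> QCReport:
    """Reject growth SDS values outside physiological plausibility bounds."""
    lo, hi = sds_bounds if sds_bounds is not None else ScoreConfig().sds_bounds
    if not lo < hi:
        raise ValueError("sds bounds must satisfy low < high")
    report = QCReport()
    for m in measures:
        report.counts_before[m.dimension] = report.counts_before.get(m.dimension, 0) + 1
        if lo <= m.sds <= hi:
            report.kept.append(m)
            report.counts_after[m.dimension] = report.counts_after.get(m.dimension, 0) + 1
        else:
            report.rejected.append((m, "implausible"))
    return report


def group_series(
    results: Sequence[LabResult],
) -> dict[tuple[str, str], list[LabResult]]:
    """Group QC-passed rows into per-patient-per-analyte series, sorted by time."""
    series: dict[tuple[str, str], list[LabResult]] = {}
    for r in results:
        series.setdefault((r.patient_id, r.analyte), []).append(r)
    for key in series:
        series[key].sort(key=lambda r: r.t_years)
    return series


def require_min_observations(
    series: Mapping[tuple[str, str], Sequence[LabResult]],
    min_n: int = 5,
    exempt: Sequence[str] = ("calprotectin",),
) -> tuple[dict[tuple[str, str], list[LabResult]], dict[tuple[str, str], TrajectoryGroup]]:
    """Apply the minimum-observation rule to each patient-analyte series.

    Returns ``(included, excluded)`` where ``excluded`` maps the failing
    (patient, analyte) keys to ``INSUFFICIENT_DATA``.  A series with
    exactly ``min_n`` observations is included.
    """
    included: dict[tuple[str, str], list[LabResult]] = {}
    excluded: dict[tuple[str, str], TrajectoryGroup] = {}
    for key, rows in series.items():
        _, analyte = key
        if analyte not in exempt and len(rows) < min_n:
            excluded[key] = TrajectoryGroup.INSUFFICIENT_DATA
            logger.info(
                "series %s/%s excluded: %d < %d observations", *key, len(rows), min_n
            )
        else:
            included[key] = list(rows)
    return included, excluded


def droppable_patients(
    series: Mapping[tuple[str, str], Sequence[LabResult]],
    blood_analytes: Sequence[str],
    min_n: int = 5,
) -> set[str]:
    """Patients whose *every* blood-analyte series fails the minimum-
    observation rule; they cannot be scored on longitudinal blood data and
    are dropped from the cohort (with a logged exclusion)."""
    per_patient: dict[str, list[bool]] = {}
    for (pid, analyte), rows in series.items():
        if analyte in blood_analytes:
            per_patient.setdefault(pid, []).append(len(rows) >= min_n)
    dropped = {pid for pid, oks in per_patient.items() if not any(oks)}
    for pid in sorted(dropped):
        logger.warning("patient %s dropped: <%d observations for every blood analyte", pid, min_n)
    return dropped


__all__ = [
    "QCReport",
    "filter_lab_results",
    "filter_growth_measures",
    "group_series",
    "require_min_observations",
    "droppable_patients",
    "EXCLUSION_QC_FLAGS",
]
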