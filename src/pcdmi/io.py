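"""Readers and writers for the tabular cohort dialects.

The package consumes EHR *exports*, not live systems:

* ``labs.csv``     — long format, one row per result:
  ``patient_id,analyte,date|t_years,value,ref_low,ref_high,qc_flags``
  (``qc_flags`` semicolon-joined; either a ``date`` or a precomputed
  ``t_years`` column);
* ``growth.csv``   — ``patient_id,dimension,date|t_years,sds``;
* ``reports.csv``  — ``patient_id,source,text,curated_stricturing,
  curated_fistulating``;
* ``registry.json``— array of patient objects carrying diagnosis date,
  follow-up years and the ever-during-follow-up booleans (medication
  classes, surgery, EIMs);
* ``config.yaml``  — a serialised :class:`~pcdmi.config.ScoreConfig`.

Rows that fail to parse are never silently dropped: every reader
returns the parsed records together with a reject list carrying the
row number and reason, and parsed + rejected always equals the input
row count.  Dates are converted to decimal years since diagnosis using
365.25-day years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pandas.errors import EmptyDataError

from .models import (
    ClinicalReport,
    Curation,
    GrowthMeasure,
    LabResult,
    PatientSummary,
    PCDMIResult,
)

DAYS_PER_YEAR = 365.25


@dataclass
class RejectedRow:
    source: str
    row: int  # 0-based data-row index
    reason: str
    raw: dict = field(default_factory=dict)


@dataclass
class RegistryEntry:
    """Static per-patient facts from the registry export."""

    patient_id: str
    followup_years: float
    diagnosis_date: Optional[date] = None
    diagnosis_year: Optional[int] = None
    meds: dict[str, bool] = field(default_factory=dict)
    surgery: dict[str, bool] = field(default_factory=dict)
    eims: dict[str, bool] = field(default_factory=dict)


@dataclass
class CohortBundle:
    """Everything read from one cohort export."""

    labs: list[LabResult] = field(default_factory=list)
    growth: list[GrowthMeasure] = field(default_factory=list)
    reports: list[ClinicalReport] = field(default_factory=list)
    registry: dict[str, RegistryEntry] = field(default_factory=dict)
    rejects: list[RejectedRow] = field(default_factory=list)


class SchemaError(ValueError):
    """A mandatory column is missing or the registry is inconsistent."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _t_years(row: pd.Series, diagnosis: Optional[date]) -> float:
    t = row.get("t_years")
    if t is not None and not pd.isna(t):
        return float(t)
    d = row.get("date")
    if d is None or pd.isna(d):
        raise ValueError("row has neither t_years nor date")
    if diagnosis is None:
        raise ValueError("date given but patient has no diagnosis_date in registry")
    parsed = datetime.fromisoformat(str(d)).date()
    return (parsed - diagnosis).days / DAYS_PER_YEAR


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_registry(path: str | Path) -> dict[str, RegistryEntry]:
    """Read the per-patient registry JSON; duplicate ids are an error."""
    raw = json.loads(Path(path).read_text())
    registry: dict[str, RegistryEntry] = {}
    for obj in raw:
        pid = str(obj["patient_id"])
        if pid in registry:
            raise SchemaError(f"{path}: duplicate patient_id {pid!r} in registry")
        diag = obj.get("diagnosis_date")
        diag_date = date.fromisoformat(diag) if diag else None
        registry[pid] = RegistryEntry(
            patient_id=pid,
            followup_years=float(obj["followup_years"]),
            diagnosis_date=diag_date,
            diagnosis_year=obj.get(
                "diagnosis_year", diag_date.year if diag_date else None
            ),
            meds={k: bool(v) for k, v in obj.get("meds", {}).items()},
            surgery={k: bool(v) for k, v in obj.get("surgery", {}).items()},
            eims={k: bool(v) for k, v in obj.get("eims", {}).items()},
        )
    return registry


def read_labs(
    path: str | Path,
    registry: Optional[dict[str, RegistryEntry]] = None,
) -> tuple[list[LabResult], list[RejectedRow]]:
    """Read the long-format lab CSV; unparseable rows go to the reject list."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "qc_flags": str})
    except EmptyDataError:
        return [], []
    _require_columns(df, ["patient_id", "analyte", "value"], str(path))
    if "t_years" not in df.columns and "date" not in df.columns:
        raise SchemaError(f"{path}: need a t_years or date column")

    results: list[LabResult] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            pid = str(row["patient_id"])
            diag = None
            if registry is not None and pid in registry:
                diag = registry[pid].diagnosis_date
            flags = row.get("qc_flags")
            flagset = frozenset(
                f.strip() for f in str(flags).split(";") if f.strip()
            ) if flags is not None and not pd.isna(flags) else frozenset()
            results.append(
                LabResult(
                    patient_id=pid,
                    analyte=str(row["analyte"]),
                    t_years=_t_years(row, diag),
                    value=_opt_float(row.get("value")),
                    ref_low=_opt_float(row.get("ref_low")),
                    ref_high=_opt_float(row.get("ref_high")),
                    qc_flags=flagset,
                )
            )
        except Exception as exc:  # collect, never drop
            rejects.append(RejectedRow("labs", int(i), str(exc), row.to_dict()))
    return results, rejects


def read_growth(
    path: str | Path,
    registry: Optional[dict[str, RegistryEntry]] = None,
) -> tuple[list[GrowthMeasure], list[RejectedRow]]:
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except EmptyDataError:
        return [], []
    _require_columns(df, ["patient_id", "dimension", "sds"], str(path))
    measures: list[GrowthMeasure] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            pid = str(row["patient_id"])
            diag = None
            if registry is not None and pid in registry:
                diag = registry[pid].diagnosis_date
            measures.append(
                GrowthMeasure(
                    patient_id=pid,
                    dimension=str(row["dimension"]),
                    t_years=_t_years(row, diag),
                    sds=float(row["sds"]),
                )
            )
        except Exception as exc:
            rejects.append(RejectedRow("growth", int(i), str(exc), row.to_dict()))
    return measures, rejects


def read_reports(path: str | Path) -> tuple[list[ClinicalReport], list[RejectedRow]]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except EmptyDataError:
        return [], []
    _require_columns(df, ["patient_id", "text"], str(path))
    reports: list[ClinicalReport] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            reports.append(
                ClinicalReport(
                    patient_id=str(row["patient_id"]),
                    source=row.get("source") or "other",
                    text=row.get("text") or "",
                    curated_stricturing=Curation(
                        row.get("curated_stricturing") or "unset"
                    ),
                    curated_fistulating=Curation(
                        row.get("curated_fistulating") or "unset"
                    ),
                )
            )
        except Exception as exc:
            rejects.append(RejectedRow("reports", int(i), str(exc), row.to_dict()))
    return reports, rejects


def read_cohort(
    labs: Optional[str | Path] = None,
    growth: Optional[str | Path] = None,
    reports: Optional[str | Path] = None,
    registry: Optional[str | Path] = None,
) -> CohortBundle:
    """Read a full cohort export into a typed bundle (any part optional)."""
    bundle = CohortBundle()
    if registry is not None:
        bundle.registry = read_registry(registry)
    if labs is not None:
        bundle.labs, rej = read_labs(labs, bundle.registry or None)
        bundle.rejects.extend(rej)
    if growth is not None:
        bundle.growth, rej = read_growth(growth, bundle.registry or None)
        bundle.rejects.extend(rej)
    if reports is not None:
        bundle.reports, rej = read_reports(reports)
        bundle.rejects.extend(rej)
    return bundle


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

#: Stable leading column order of the results CSV.
RESULT_COLUMNS = [
    "patient_id",
    "base_score",
    "coefficient",
    "adjusted_score",
    "followup_years",
    "missing",
]


def write_results(results: Sequence[PCDMIResult], path: str | Path) -> None:
    """Write per-patient results with the full component breakdown.

    Adjusted scores are rounded to one decimal on output (scores are
    reported like 32.5 or 2.2); the breakdown columns carry the exact
    component points, so the base score remains an exact sum.
    """
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "base_score": r.base_score,
            "coefficient": r.coefficient,
            "adjusted_score": round(r.adjusted_score, 1),
            "followup_years": r.followup_years,
            "missing": ";".join(r.missing),
        }
        for comp in sorted(r.components):
            row[f"component.{comp}"] = r.components[comp]
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = [c for c in RESULT_COLUMNS if c in df.columns]
    rest = sorted(c for c in df.columns if c not in lead)
    df = df[lead + rest]
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> list[PCDMIResult]:
    """Round-trip reader for :func:`write_results` output."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: list[PCDMIResult] = []
    for _, row in df.iterrows():
        components = {
            c[len("component."):]: float(row[c])
            for c in df.columns
            if c.startswith("component.")
        }
        missing = row.get("missing")
        base = float(row["base_score"])
        coeff = float(row["coefficient"])
        out.append(
            PCDMIResult(
                patient_id=str(row["patient_id"]),
                components=components,
                missing=(
                    [] if missing is None or pd.isna(missing) or missing == ""
                    else str(missing).split(";")
                ),
                base_score=base,
                coefficient=coeff,
                adjusted_score=base * coeff,
                followup_years=float(row["followup_years"]),
            )
        )
    return out


def summaries_from_bundle(
    bundle: CohortBundle,
    trajectory: dict[tuple[str, str], "object"],
    complications: dict[str, "object"],
    growth_flags: dict[tuple[str, str], bool],
) -> list[PatientSummary]:
    """Assemble scoring inputs from classified cohort pieces.

    ``growth_flags`` maps (patient_id, dimension) to the triggered flag;
    a patient-dimension absent from the map is treated as a missing
    component.
    """
    summaries = []
    for pid, entry in bundle.registry.items():
        traj = {
            analyte: group
            for (p, analyte), group in trajectory.items()
            if p == pid
        }
        pheno = complications.get(pid)
        comp = {
            "stricturing": bool(getattr(pheno, "stricturing", False)),
            "fistulating": bool(getattr(pheno, "fistulating", False)),
        }
        gf: dict[str, bool] = {}
        for dim, key in (("weight", "weight_flag"), ("height", "height_flag")):
            if (pid, dim) in growth_flags:
                gf[key] = growth_flags[(pid, dim)]
        summaries.append(
            PatientSummary(
                patient_id=pid,
                followup_years=entry.followup_years,
                diagnosis_date=entry.diagnosis_date,
                trajectory=traj,
                meds=entry.meds,
                complications=comp,
                surgery=entry.surgery,
                growth_flags=gf,
                eims=entry.eims,
            )
        )
    return summaries


__all__ = [
    "CohortBundle",
    "RegistryEntry",
    "RejectedRow",
    "SchemaError",
    "read_registry",
    "read_labs",
    "read_growth",
    "read_reports",
    "read_cohort",
    "write_results",
    "read_results",
    "summaries_from_bundle",
    "DAYS_PER_YEAR",
]
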