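"""End-to-end orchestration: cohort bundle in, scored results out.

Runs the stages in order: lab and growth QC, the minimum-observation
rule, trajectory classification, phenotype assignment, growth-flag
assessment, then per-patient score computation.  Patients whose every
blood-analyte series fails the minimum-observation rule are dropped
from scoring (they cannot be assessed on longitudinal blood data);
individual insufficient series merely mark that component missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import ScoreConfig
from .io import CohortBundle
from .models import PCDMIResult, PatientSummary, TrajectoryGroup
from .phenotype_text import assign_cohort_phenotypes
from .quality_control import (
    droppable_patients,
    filter_growth_measures,
    filter_lab_results,
    group_series,
    require_min_observations,
)
from .scoring import assess_growth, compute_pcdmi
from .trajectory import AbnormalitySeries, classify_series


@dataclass
class PipelineOutput:
    results: list[PCDMIResult] = field(default_factory=list)
    summaries: list[PatientSummary] = field(default_factory=list)
    dropped_patients: set[str] = field(default_factory=set)
    lab_rejects: list = field(default_factory=list)
    growth_rejects: list = field(default_factory=list)
    trajectories: dict[tuple[str, str], TrajectoryGroup] = field(default_factory=dict)


def score_cohort(
    bundle: CohortBundle, config: Optional[ScoreConfig] = None
) -> PipelineOutput:
    config = config or ScoreConfig()
    out = PipelineOutput()

    lab_qc = filter_lab_results(bundle.labs, config=config)
    out.lab_rejects = lab_qc.rejected
    growth_qc = filter_growth_measures(bundle.growth, config.sds_bounds)
    out.growth_rejects = growth_qc.rejected

    series = group_series(lab_qc.kept)
    included, insufficient = require_min_observations(
        series, min_n=config.min_observations, exempt=config.min_obs_exempt
    )
    out.trajectories.update(insufficient)
    out.dropped_patients = droppable_patients(
        series, config.blood_analytes(), min_n=config.min_observations
    )

    followup = {pid: e.followup_years for pid, e in bundle.registry.items()}
    for (pid, analyte), rows in included.items():
        if pid not in followup:
            continue  # labs for a patient absent from the registry
        abn = AbnormalitySeries.from_results(rows, followup_years=followup[pid])
        out.trajectories[(pid, analyte)] = classify_series(
            abn, window_years=config.normalization_window_years
        )

    phenotypes = assign_cohort_phenotypes(bundle.reports, bundle.registry.keys())

    growth_by_patient_dim: dict[tuple[str, str], list] = {}
    for m in growth_qc.kept:
        growth_by_patient_dim.setdefault((m.patient_id, m.dimension), []).append(m)
    growth_flags: dict[tuple[str, str], bool] = {}
    for key, measures in growth_by_patient_dim.items():
        growth_flags[key] = assess_growth(measures).triggered

    for pid, entry in bundle.registry.items():
        if pid in out.dropped_patients:
            continue
        traj = {
            analyte: group
            for (p, analyte), group in out.trajectories.items()
            if p == pid
        }
        pheno = phenotypes[pid]
        gf: dict[str, bool] = {}
        for dim, key in (("weight", "weight_flag"), ("height", "height_flag")):
            if (pid, dim) in growth_flags:
                gf[key] = growth_flags[(pid, dim)]
        summary = PatientSummary(
            patient_id=pid,
            followup_years=entry.followup_years,
            diagnosis_date=entry.diagnosis_date,
            trajectory=traj,
            meds=entry.meds,
            complications={
                "stricturing": pheno.stricturing,
                "fistulating": pheno.fistulating,
            },
            surgery=entry.surgery,
            growth_flags=gf,
            eims=entry.eims,
        )
        out.summaries.append(summary)
        out.results.append(compute_pcdmi(summary, config))
    return out


__all__ = ["PipelineOutput", "score_cohort"]
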