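"""Synthetic cohort generation with known ground truth.

No pediatric Crohn EHR cohort is publicly deposited, so every pipeline
stage is exercised against generated cohorts whose intended trajectory
groups, phenotypes and scores are known exactly.  The generator draws,
per patient:

* a follow-up duration (default uniform on 2-10.5 years, the
  neighbourhood of routinely observed pediatric follow-up);
* a trajectory group per analyte from a configurable mixture, then
  realises a lab series whose abnormality-flag pattern is *guaranteed*
  to classify into that group (values are drawn uniformly inside or
  outside the reference interval as the pattern requires — only the
  flag pattern drives the score, so no physiological realism beyond
  flags is attempted);
* calprotectin series that are deliberately sparse and never normal at
  diagnosis, mirroring routine stool sampling;
* a growth scenario per dimension (no growth failure, a >1.0 SDS fall,
  a drop below -2.0 SDS, or no improvement from a baseline below -2.0)
  realised as an SDS series that triggers exactly the intended rule;
* medication-class, complication, surgery and EIM booleans from
  prevalences, with report snippets containing complicated-disease
  keywords iff the complication was assigned.

Expected scores in the ground truth are computed by direct summation
over the intended assignments — an independent tally, not a call into
the scoring module — so end-to-end tests compare two separate routes to
the same number.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import DEFAULT_REFERENCE_INTERVALS, ScoreConfig
from .io import CohortBundle, RegistryEntry
from .models import (
    COMPLICATIONS,
    DEFAULT_ANALYTES,
    EIMS,
    MED_CLASSES,
    SURGERIES,
    ClinicalReport,
    GrowthMeasure,
    LabResult,
    TrajectoryGroup,
)

_PN = TrajectoryGroup.PERSISTENTLY_NORMAL
_NM = TrajectoryGroup.NORMALIZED
_RR = TrajectoryGroup.RELAPSING_REMITTING

# report snippets; "benign" texts must contain no phenotype keyword
STRICTURING_TEMPLATES = (
    "MRI small bowel: tight stricture in the terminal ileum with pre-stenotic dilatation.",
    "Endoscopy: fibrotic narrowing of the ileocaecal valve, scope not passable.",
    "Ultrasound: segmental thickening with reduced diameter of the distal ileum.",
)
FISTULATING_TEMPLATES = (
    "MRI pelvis: trans-sphincteric fistula with a small collection.",
    "Examination: enterocutaneous fistulae noted adjacent to the stoma site.",
    "CT abdomen: penetrating disease with an abnormal connection to the bladder wall.",
)
BENIGN_TEMPLATES = (
    "Colonoscopy: patchy erythema in the ascending colon, biopsies taken.",
    "Clinic letter: doing well on current therapy, no new symptoms reported.",
    "MRI small bowel: mild mural thickening of the terminal ileum, no complication.",
)


class GrowthScenario:
    NONE = "none"
    FALL = "fall_gt_1sd"
    BELOW2 = "dropped_below_minus2"
    NO_IMPROVEMENT = "no_improvement_from_below_minus2"
    MISSING = "missing"


class SimConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = Field(default=66, gt=0)
    followup_range: tuple[float, float] = (2.0, 10.5)
    diagnosis_years: tuple[int, int] = (2012, 2019)
    # trajectory-group mixture (persistently normal, normalized,
    # relapsing-remitting) per analyte; calprotectin is never normal at
    # diagnosis, so its persistently-normal weight is 0
    blood_mixture: tuple[float, float, float] = (0.45, 0.25, 0.30)
    calprotectin_mixture: tuple[float, float, float] = (0.0, 0.45, 0.55)
    blood_obs_per_year: float = 6.0
    calprotectin_mean_extra_obs: float = 2.2  # series length 1 + Poisson(.)
    min_blood_obs: int = 5
    # prevalences ("ever during follow-up")
    med_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "asa_topical": 0.50,
            "immunomodulator": 0.70,
            "first_line_monoclonal": 0.40,
            "second_line_monoclonal_or_small_molecule": 0.15,
        }
    )
    complication_prevalence: dict[str, float] = Field(
        default_factory=lambda: {"stricturing": 0.15, "fistulating": 0.10}
    )
    surgery_prevalence: dict[str, float] = Field(
        default_factory=lambda: {"intestinal_resection": 0.15, "perianal_procedure": 0.10}
    )
    eim_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "liver": 0.04, "skin": 0.04, "eye": 0.03,
            "arthritis": 0.05, "other_autoimmune": 0.02,
        }
    )
    growth_scenario_probs: dict[str, float] = Field(
        default_factory=lambda: {
            GrowthScenario.NONE: 0.84,
            GrowthScenario.FALL: 0.06,
            GrowthScenario.BELOW2: 0.07,
            GrowthScenario.NO_IMPROVEMENT: 0.03,
            GrowthScenario.MISSING: 0.0,
        }
    )
    growth_obs_per_year: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.followup_range
        if not 0 < lo < hi:
            raise ValueError("followup_range must be ordered and positive")
        for name in ("blood_mixture", "calprotectin_mixture"):
            mix = getattr(self, name)
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for name in ("med_prevalence", "complication_prevalence",
                     "surgery_prevalence", "eim_prevalence"):
            if any(not 0 <= p <= 1 for p in getattr(self, name).values()):
                raise ValueError(f"{name} values must lie in [0, 1]")
        probs = self.growth_scenario_probs
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("growth_scenario_probs must be non-negative and sum to 1")
        if lo < 1.0 and (self.blood_mixture[1] > 0 or self.calprotectin_mixture[1] > 0):
            # normalized series need room for the post-window normal tail
            raise ValueError(
                "NORMALIZED mixture requires followup_range to start at >= "
                "the normalisation window"
            )
        return self


@dataclass
class GroundTruth:
    """Intended assignments and independently summed expected scores."""

    patient_id: str
    followup_years: float
    diagnosis_year: int
    trajectory: dict[str, str] = field(default_factory=dict)
    meds: dict[str, bool] = field(default_factory=dict)
    complications: dict[str, bool] = field(default_factory=dict)
    surgery: dict[str, bool] = field(default_factory=dict)
    growth_flags: dict[str, bool] = field(default_factory=dict)
    growth_scenarios: dict[str, str] = field(default_factory=dict)
    eims: dict[str, bool] = field(default_factory=dict)
    expected_components: dict[str, float] = field(default_factory=dict)
    expected_base: float = 0.0
    expected_coefficient: float = 1.0
    expected_adjusted: float = 0.0


# ---------------------------------------------------------------------------
# series realisation
# ---------------------------------------------------------------------------

def _draw_value(
    rng: np.random.Generator,
    analyte: str,
    abnormal: bool,
    score_config: ScoreConfig,
) -> float:
    """Uniform draw inside or outside the reference interval.

    Abnormal values stay on the abnormal side of the interval but inside
    the physiological-plausibility bounds, so QC keeps them.
    """
    lo, hi = DEFAULT_REFERENCE_INTERVALS[analyte]
    plo, phi = score_config.plausibility_bounds[analyte]
    if not abnormal:
        a = lo if lo is not None else plo
        b = hi if hi is not None else phi
        return float(rng.uniform(a, b))
    if lo is not None and lo - plo > 1.0:  # deficit (anemia, hypoalbuminaemia)
        return float(rng.uniform(plo + 0.5 * (lo - plo), lo - 0.02 * (lo - plo)))
    assert hi is not None
    return float(rng.uniform(hi + 0.05 * (phi - hi), hi + 0.6 * (phi - hi)))


def _realise_lab_series(
    rng: np.random.Generator,
    pid: str,
    analyte: str,
    group: TrajectoryGroup,
    followup: float,
    n_obs: int,
    window: float,
    score_config: ScoreConfig,
) -> list[LabResult]:
    """Times and abnormality flags guaranteed to classify as ``group``."""
    ref = DEFAULT_REFERENCE_INTERVALS[analyte]
    times: list[float]
    flags: list[bool]
    if group is _PN:
        times = sorted(rng.uniform(0.0, followup, size=n_obs).tolist())
        flags = [False] * n_obs
    elif group is _NM:
        # abnormal prefix confined to the first part of the window, then a
        # normal tail strictly after the last abnormal result
        n_abn = int(rng.integers(1, min(n_obs, 3) + 1))
        n_norm = n_obs - n_abn
        t_abn = sorted(rng.uniform(0.0, 0.4 * window, size=n_abn).tolist())
        t_norm = sorted(rng.uniform(0.5 * window, followup, size=n_norm).tolist())
        times = t_abn + t_norm
        flags = [True] * n_abn + [False] * n_norm
    elif group is _RR:
        # abnormal at diagnosis, recovery, then recurrence after the window
        times = sorted(rng.uniform(0.0, followup, size=n_obs).tolist())
        times[0] = float(rng.uniform(0.0, 0.1 * window))
        t_late = float(rng.uniform(min(window * 1.05, followup * 0.98), followup))
        times[-1] = t_late
        times = sorted(times)
        flags = [bool(rng.random() < 0.4) for _ in times]
        flags[0] = True
        # force one abnormal strictly after the window (or ongoing
        # inflammation at the last observation under short follow-up)
        late = [i for i, t in enumerate(times) if t > window]
        flags[late[-1] if late else len(times) - 1] = True
    else:
        raise ValueError(f"cannot realise group {group}")
    return [
        LabResult(
            patient_id=pid,
            analyte=analyte,
            t_years=round(t, 4),
            value=round(_draw_value(rng, analyte, abn, score_config), 2),
            ref_low=ref[0],
            ref_high=ref[1],
        )
        for t, abn in zip(times, flags)
    ]


def _realise_growth_series(
    rng: np.random.Generator,
    pid: str,
    dimension: str,
    scenario: str,
    followup: float,
    obs_per_year: float,
) -> tuple[list[GrowthMeasure], bool]:
    n = max(3, int(round(obs_per_year * followup)))
    times = [0.0] + sorted(rng.uniform(0.1, followup, size=n - 1).tolist())
    if scenario == GrowthScenario.NONE:
        b = float(rng.uniform(-1.5, 1.5))
        lo = max(b - 0.9, -1.9)
        sds = [b] + [float(rng.uniform(lo, b + 1.0)) for _ in times[1:]]
        triggered = False
    elif scenario == GrowthScenario.FALL:
        b = float(rng.uniform(0.0, 1.5))
        dip = b - float(rng.uniform(1.1, 1.8))
        sds = [b] + [float(rng.uniform(b - 0.5, b + 0.5)) for _ in times[1:-1]] + [dip]
        triggered = True
    elif scenario == GrowthScenario.BELOW2:
        b = float(rng.uniform(-1.9, -1.5))
        dip = float(rng.uniform(max(b - 0.9, -2.4), -2.05))
        sds = [b] + [float(rng.uniform(b - 0.3, b + 0.5)) for _ in times[1:-1]] + [dip]
        triggered = True
    elif scenario == GrowthScenario.NO_IMPROVEMENT:
        b = float(rng.uniform(-3.0, -2.2))
        final = b - float(rng.uniform(0.0, 0.4))
        sds = [b] + [float(rng.uniform(b - 0.4, b + 0.4)) for _ in times[1:-1]] + [final]
        triggered = True
    else:
        raise ValueError(f"unknown growth scenario {scenario!r}")
    measures = [
        GrowthMeasure(patient_id=pid, dimension=dimension, t_years=round(t, 4), sds=round(s, 3))
        for t, s in zip(times, sds)
    ]
    return measures, triggered


# ---------------------------------------------------------------------------
# independent expected-score tally
# ---------------------------------------------------------------------------

def _expected_score(
    gt: GroundTruth, score_config: ScoreConfig
) -> tuple[dict[str, float], float, float, float]:
    """Direct summation over intended assignments (no scoring-module call)."""
    w = score_config.weights
    tp = score_config.trajectory_points
    comps: dict[str, float] = {}
    for analyte, label in gt.trajectory.items():
        comps[analyte] = tp[TrajectoryGroup(label)]
    for booleans in (gt.meds, gt.complications, gt.surgery, gt.eims):
        for key, on in booleans.items():
            comps[key] = w[key] if on else 0.0
    for key, on in gt.growth_flags.items():
        comps[key] = w[key] if on else 0.0
    base = sum(comps.values())
    coeff = None
    for band in score_config.coefficient_bands:
        if band.lower <= gt.followup_years < band.upper:
            coeff = band.multiplier
            break
    assert coeff is not None
    return comps, base, coeff, base * coeff


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _pick_group(rng: np.random.Generator, mixture: tuple[float, float, float]) -> TrajectoryGroup:
    return (_PN, _NM, _RR)[int(rng.choice(3, p=np.asarray(mixture)))]


def generate_cohort(
    config: SimConfig,
    score_config: Optional[ScoreConfig] = None,
    seed: int = 0,
) -> tuple[CohortBundle, dict[str, GroundTruth]]:
    """Generate a full cohort bundle plus its ground truth.

    The (config, seed) pair fully determines the output.
    """
    score_config = score_config or ScoreConfig()
    rng = np.random.default_rng(seed)
    window = score_config.normalization_window_years
    if config.followup_range[0] < 1.05 * window:
        raise ValueError(
            "contradictory config: follow-up must clear the normalisation "
            "window so post-window behaviour is observable"
        )
    bundle = CohortBundle()
    truths: dict[str, GroundTruth] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        followup = float(rng.uniform(*config.followup_range))
        year = int(rng.integers(config.diagnosis_years[0], config.diagnosis_years[1] + 1))
        diag = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        gt = GroundTruth(patient_id=pid, followup_years=round(followup, 3), diagnosis_year=year)

        for analyte in DEFAULT_ANALYTES:
            if analyte == "calprotectin":
                group = _pick_group(rng, config.calprotectin_mixture)
                n_obs = 1 + int(rng.poisson(config.calprotectin_mean_extra_obs))
                if group is _RR:
                    n_obs = max(n_obs, 2)  # needs a post-window abnormal
            else:
                group = _pick_group(rng, config.blood_mixture)
                n_obs = max(
                    config.min_blood_obs,
                    int(rng.poisson(config.blood_obs_per_year * followup)),
                )
            gt.trajectory[analyte] = group.value
            bundle.labs.extend(
                _realise_lab_series(
                    rng, pid, analyte, group, followup, n_obs, window, score_config
                )
            )

        for dim, key in (("weight", "weight_flag"), ("height", "height_flag")):
            scen = str(
                rng.choice(
                    list(config.growth_scenario_probs),
                    p=list(config.growth_scenario_probs.values()),
                )
            )
            gt.growth_scenarios[dim] = scen
            if scen == GrowthScenario.MISSING:
                continue
            measures, triggered = _realise_growth_series(
                rng, pid, dim, scen, followup, config.growth_obs_per_year
            )
            bundle.growth.extend(measures)
            gt.growth_flags[key] = triggered

        gt.meds = {k: bool(rng.random() < p) for k, p in config.med_prevalence.items()}
        gt.complications = {
            k: bool(rng.random() < p) for k, p in config.complication_prevalence.items()
        }
        gt.surgery = {k: bool(rng.random() < p) for k, p in config.surgery_prevalence.items()}
        gt.eims = {k: bool(rng.random() < p) for k, p in config.eim_prevalence.items()}

        if gt.complications.get("stricturing"):
            bundle.reports.append(
                ClinicalReport(
                    patient_id=pid,
                    source="mri",
                    text=str(rng.choice(STRICTURING_TEMPLATES)),
                )
            )
        if gt.complications.get("fistulating"):
            bundle.reports.append(
                ClinicalReport(
                    patient_id=pid,
                    source="mri",
                    text=str(rng.choice(FISTULATING_TEMPLATES)),
                )
            )
        if not any(gt.complications.values()) and rng.random() < 0.5:
            bundle.reports.append(
                ClinicalReport(
                    patient_id=pid,
                    source="clinic_letter",
                    text=str(rng.choice(BENIGN_TEMPLATES)),
                )
            )

        bundle.registry[pid] = RegistryEntry(
            patient_id=pid,
            followup_years=gt.followup_years,
            diagnosis_date=diag,
            diagnosis_year=year,
            meds=dict(gt.meds),
            surgery=dict(gt.surgery),
            eims=dict(gt.eims),
        )

        comps, base, coeff, adjusted = _expected_score(gt, score_config)
        gt.expected_components = comps
        gt.expected_base = base
        gt.expected_coefficient = coeff
        gt.expected_adjusted = adjusted
        truths[pid] = gt

    return bundle, truths


# ---------------------------------------------------------------------------
# QC contamination
# ---------------------------------------------------------------------------

def inject_qc_noise(
    bundle: CohortBundle,
    hemolyzed_rate: float = 0.0,
    implausible_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CohortBundle, list[LabResult]]:
    """Append contaminated lab rows; return the new bundle and the ledger.

    Original rows are untouched: the QC filter must reject exactly the
    ledger, leaving the original rows (in order) as the kept stream.
    """
    if not 0 <= hemolyzed_rate < 1 or not 0 <= implausible_rate < 1:
        raise ValueError("contamination rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ledger: list[LabResult] = []
    for row in bundle.labs:
        if rng.random() < hemolyzed_rate:
            ledger.append(
                row.model_copy(update={"qc_flags": frozenset({"hemolyzed"}), "value": None})
            )
        if rng.random() < implausible_rate:
            ledger.append(row.model_copy(update={"value": 1e7}))
    contaminated = CohortBundle(
        labs=list(bundle.labs) + ledger,
        growth=list(bundle.growth),
        reports=list(bundle.reports),
        registry=dict(bundle.registry),
        rejects=list(bundle.rejects),
    )
    return contaminated, ledger


# ---------------------------------------------------------------------------
# serialisation and canonical example patients
# ---------------------------------------------------------------------------

def write_bundle(
    bundle: CohortBundle,
    truths: dict[str, GroundTruth],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the bundle in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    labs = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "analyte": r.analyte,
                "t_years": r.t_years,
                "value": r.value,
                "ref_low": r.ref_low,
                "ref_high": r.ref_high,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
            for r in bundle.labs
        ]
    )
    growth = pd.DataFrame(
        [
            {"patient_id": m.patient_id, "dimension": m.dimension,
             "t_years": m.t_years, "sds": m.sds}
            for m in bundle.growth
        ]
    )
    reports = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "source": r.source,
                "text": r.text,
                "curated_stricturing": r.curated_stricturing.value,
                "curated_fistulating": r.curated_fistulating.value,
            }
            for r in bundle.reports
        ]
    )
    registry = [
        {
            "patient_id": e.patient_id,
            "followup_years": e.followup_years,
            "diagnosis_date": e.diagnosis_date.isoformat() if e.diagnosis_date else None,
            "diagnosis_year": e.diagnosis_year,
            "meds": e.meds,
            "surgery": e.surgery,
            "eims": e.eims,
        }
        for e in bundle.registry.values()
    ]
    paths = {
        "labs": outdir / "labs.csv",
        "growth": outdir / "growth.csv",
        "reports": outdir / "reports.csv",
        "registry": outdir / "registry.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    labs.to_csv(paths["labs"], index=False)
    growth.to_csv(paths["growth"], index=False)
    reports.to_csv(paths["reports"], index=False)
    paths["registry"].write_text(json.dumps(registry, indent=1))
    paths["ground_truth"].write_text(
        json.dumps({pid: asdict(gt) for pid, gt in truths.items()}, indent=1)
    )
    return paths


def maximal_patient_summary(
    followup_years: float, include_other_autoimmune: bool = False
):
    """The maximal-burden patient: every standard component at maximum.

    All five lab/stool series relapsing-remitting, all four medication
    classes, both complications, both surgeries, both growth flags and
    the four named EIM categories; the fifth EIM category (other
    autoimmune comorbidity) is off unless requested.
    """
    from .models import PatientSummary

    return PatientSummary(
        patient_id="maximal",
        followup_years=followup_years,
        trajectory={a: _RR for a in DEFAULT_ANALYTES},
        meds={k: True for k in MED_CLASSES},
        complications={k: True for k in COMPLICATIONS},
        surgery={k: True for k in SURGERIES},
        growth_flags={"weight_flag": True, "height_flag": True},
        eims={
            k: (k != "other_autoimmune" or include_other_autoimmune) for k in EIMS
        },
    )


def quiescent_patient_summary(followup_years: float):
    """The all-quiescent patient: persistently normal labs, nothing else."""
    from .models import PatientSummary

    return PatientSummary(
        patient_id="quiescent",
        followup_years=followup_years,
        trajectory={a: _PN for a in DEFAULT_ANALYTES},
        meds={k: False for k in MED_CLASSES},
        complications={k: False for k in COMPLICATIONS},
        surgery={k: False for k in SURGERIES},
        growth_flags={"weight_flag": False, "height_flag": False},
        eims={k: False for k in EIMS},
    )


__all__ = [
    "SimConfig",
    "GroundTruth",
    "GrowthScenario",
    "generate_cohort",
    "inject_qc_noise",
    "write_bundle",
    "maximal_patient_summary",
    "quiescent_patient_summary",
]
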