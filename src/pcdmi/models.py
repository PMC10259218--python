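"""Domain types for the PCD-MI scoring pipeline.

The Pediatric Crohn Disease Morbidity Index (PCD-MI) is a composite
longitudinal disease-burden score for pediatric Crohn disease.  It is
computed from five themes of routinely collected clinical data:
longitudinal blood/stool laboratory trajectories, long-term medication
use, complicated disease behaviour (stricturing/fistulating), surgery,
growth (height/weight standard-deviation scores), and extraintestinal
manifestations (EIMs).

These models are deliberately plain: they mirror the tabular EHR export
dialects the package reads (long-format lab CSV, growth CSV, report CSV,
patient registry JSON) and carry just enough validation to catch
malformed exports early.
"""

from __future__ import annotations

import enum
from datetime import date
from typing import Optional

from pydantic import BaseModel, Field, model_validator

# Analytes scored by default.  The registry is extensible: any series that
# represents inflammation or disease activity can be classified the same
# way, but the default weight table covers exactly these five.
BLOOD_ANALYTES = ("hemoglobin", "crp", "platelets", "albumin")
STOOL_ANALYTES = ("calprotectin",)
DEFAULT_ANALYTES = BLOOD_ANALYTES + STOOL_ANALYTES

#: QC flags that exclude a laboratory row from downstream analysis.
EXCLUSION_QC_FLAGS = frozenset(
    {
        "hemolyzed",
        "insufficient_sample",
        "failed_test",
        "sample_not_received",
        "clotted",
        "implausible",
    }
)

# Small tolerance for results timestamped just before the recorded
# diagnosis date (diagnostic work-up samples).
PRE_DIAGNOSIS_TOLERANCE_YEARS = 0.1


class TrajectoryGroup(str, enum.Enum):
    """Three-level classification of a longitudinal abnormality series.

    ``PERSISTENTLY_NORMAL``  -- every result normal, including at diagnosis.
    ``NORMALIZED``           -- initially abnormal, normalises within the
                                normalisation window (default 1 year) and
                                stays normal.
    ``RELAPSING_REMITTING``  -- abnormality recurring or persisting over
                                the disease course.
    ``INSUFFICIENT_DATA``    -- series failed the minimum-observation rule
                                and cannot be classified.
    """

    PERSISTENTLY_NORMAL = "persistently_normal"
    NORMALIZED = "normalized"
    RELAPSING_REMITTING = "relapsing_remitting"
    INSUFFICIENT_DATA = "insufficient_data"


class Curation(str, enum.Enum):
    """Tri-state clinician override for a keyword-derived phenotype."""

    UNSET = "unset"
    CONFIRMED = "confirmed"
    REFUTED = "refuted"


class LabResult(BaseModel):
    """One timestamped analyte measurement with its reference interval."""

    patient_id: str
    analyte: str
    t_years: float = Field(ge=-PRE_DIAGNOSIS_TOLERANCE_YEARS)
    value: Optional[float] = None
    ref_low: Optional[float] = None
    ref_high: Optional[float] = None
    qc_flags: frozenset[str] = frozenset()

    @model_validator(mode="after")
    def _check(self) -> "LabResult":
        if self.ref_low is not None and self.ref_high is not None:
            if not self.ref_low < self.ref_high:
                raise ValueError(
                    f"ref_low must be < ref_high (got {self.ref_low}, {self.ref_high})"
                )
        unknown = self.qc_flags - EXCLUSION_QC_FLAGS
        if unknown:
            raise ValueError(f"unknown qc_flags: {sorted(unknown)}")
        if self.value is None and not self.qc_flags:
            raise ValueError("missing value without a qc_flag explaining it")
        return self

    def has_reference_range(self) -> bool:
        return self.ref_low is not None or self.ref_high is not None


class GrowthMeasure(BaseModel):
    """One height or weight standard-deviation score (SDS) measurement."""

    patient_id: str
    dimension: str  # "height" | "weight"
    t_years: float
    sds: float

    @model_validator(mode="after")
    def _check(self) -> "GrowthMeasure":
        if self.dimension not in ("height", "weight"):
            raise ValueError(f"dimension must be height|weight, got {self.dimension!r}")
        return self


class ClinicalReport(BaseModel):
    """Free-text snippet from an endoscopy/imaging report or clinic letter.

    ``curated_*`` fields carry the clinician's manual verdict; when set
    they override whatever the keyword search found.
    """

    patient_id: str
    source: str = "other"
    text: str = ""
    curated_stricturing: Curation = Curation.UNSET
    curated_fistulating: Curation = Curation.UNSET


MED_CLASSES = (
    "asa_topical",
    "immunomodulator",
    "first_line_monoclonal",
    "second_line_monoclonal_or_small_molecule",
)
COMPLICATIONS = ("stricturing", "fistulating")
SURGERIES = ("intestinal_resection", "perianal_procedure")
GROWTH_FLAGS = ("weight_flag", "height_flag")
EIMS = ("liver", "skin", "eye", "arthritis", "other_autoimmune")


class PatientSummary(BaseModel):
    """The scoring engine's input: everything known about one patient.

    All booleans have "ever during follow-up" semantics: medication use,
    complications, surgery and EIMs are coded as having occurred at any
    point, not as current status.
    """

    patient_id: str
    followup_years: float = Field(gt=0)
    diagnosis_date: Optional[date] = None
    trajectory: dict[str, TrajectoryGroup] = Field(default_factory=dict)
    meds: dict[str, bool] = Field(default_factory=dict)
    complications: dict[str, bool] = Field(default_factory=dict)
    surgery: dict[str, bool] = Field(default_factory=dict)
    growth_flags: dict[str, bool] = Field(default_factory=dict)
    eims: dict[str, bool] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PatientSummary":
        for field, allowed in (
            ("meds", MED_CLASSES),
            ("complications", COMPLICATIONS),
            ("surgery", SURGERIES),
            ("growth_flags", GROWTH_FLAGS),
            ("eims", EIMS),
        ):
            unknown = set(getattr(self, field)) - set(allowed)
            if unknown:
                raise ValueError(f"unknown {field} keys: {sorted(unknown)}")
        return self


class PCDMIResult(BaseModel):
    """Per-patient score breakdown.

    ``base_score`` is the exact sum of the component map; ``adjusted_score``
    is ``base_score * coefficient`` kept at full precision — rounding to one
    decimal happens only when results are written out.  ``missing``
    enumerates components that could not be assessed (insufficient lab
    data, no growth measures); they contribute 0 but are marked so cohort
    summaries can report completeness.
    """

    patient_id: str
    components: dict[str, float]
    missing: list[str] = Field(default_factory=list)
    base_score: float
    coefficient: float
    adjusted_score: float
    followup_years: float

    @model_validator(mode="after")
    def _check(self) -> "PCDMIResult":
        total = sum(self.components.values())
        if abs(total - self.base_score) > 1e-9:
            raise ValueError("base_score must equal the sum of components")
        if abs(self.base_score * self.coefficient - self.adjusted_score) > 1e-9:
            raise ValueError("adjusted_score must equal base_score * coefficient")
        return self
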