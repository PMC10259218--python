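"""Score configuration: component weights, coefficient bands, QC bounds.

The default weight table awards, per patient:

=====================================  ======
component                              points
=====================================  ======
each lab/stool trajectory (x5)         0/1/3
5-ASA / topical treatment              1
immunomodulator                        2
first-line monoclonal                  3
second-line monoclonal/small molecule  4
fistulating disease                    3
stricturing disease                    3
intestinal resection (ever)            4
perianal procedure (ever)              2
weight growth flag                     2
height growth flag                     2
autoimmune liver disease               3
chronic skin disease                   2
autoimmune eye disease                 2
arthritis (peripheral or axial)        2
other autoimmune comorbidity           2
=====================================  ======

Medication classes are additive (each class ever used scores), so the
standard maximum — all five series relapsing-remitting, all four
medication classes, both complications, both surgeries, both growth
flags and the four named EIM categories — is exactly 50.  A fifth EIM
(other autoimmune comorbidity) can push an individual above 50.

The follow-up coefficient bands upweight scores accrued over short
follow-up so burdens are comparable across durations; bands are
half-open ``[lower, upper)``, so exactly 3.0 years falls in the
3-5-year band.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .models import (
    COMPLICATIONS,
    DEFAULT_ANALYTES,
    EIMS,
    GROWTH_FLAGS,
    MED_CLASSES,
    SURGERIES,
    TrajectoryGroup,
)

DEFAULT_TRAJECTORY_POINTS: dict[TrajectoryGroup, float] = {
    TrajectoryGroup.PERSISTENTLY_NORMAL: 0.0,
    TrajectoryGroup.NORMALIZED: 1.0,
    TrajectoryGroup.RELAPSING_REMITTING: 3.0,
}

DEFAULT_WEIGHTS: dict[str, float] = {
    "asa_topical": 1.0,
    "immunomodulator": 2.0,
    "first_line_monoclonal": 3.0,
    "second_line_monoclonal_or_small_molecule": 4.0,
    "fistulating": 3.0,
    "stricturing": 3.0,
    "intestinal_resection": 4.0,
    "perianal_procedure": 2.0,
    "weight_flag": 2.0,
    "height_flag": 2.0,
    "liver": 3.0,
    "skin": 2.0,
    "eye": 2.0,
    "arthritis": 2.0,
    "other_autoimmune": 2.0,
}

DEFAULT_COEFFICIENT_BANDS: list[tuple[float, float, float]] = [
    (0.0, 1.0, 2.0),
    (1.0, 3.0, 1.5),
    (3.0, 5.0, 1.25),
    (5.0, 10.0, 1.1),
    (10.0, math.inf, 1.0),
]

# Pediatric-plausible physiological bounds used for QC.  The originating
# QC pipeline is site-specific; these defaults are deliberately wide and
# fully configurable — they are scaffolding, not clinical claims.
DEFAULT_PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "hemoglobin": (30.0, 250.0),  # g/L
    "crp": (0.0, 500.0),  # mg/L
    "platelets": (5.0, 2000.0),  # x10^9/L
    "albumin": (5.0, 70.0),  # g/L
    "calprotectin": (0.0, 6000.0),  # ug/g
}

DEFAULT_SDS_BOUNDS: tuple[float, float] = (-5.0, 5.0)

# Pediatric-plausible reference intervals, used only by the synthetic
# cohort generator to realise values on either side of a normal range.
DEFAULT_REFERENCE_INTERVALS: dict[str, tuple[Optional[float], Optional[float]]] = {
    "hemoglobin": (110.0, 160.0),
    "crp": (None, 5.0),
    "platelets": (150.0, 450.0),
    "albumin": (35.0, 50.0),
    "calprotectin": (None, 50.0),
}


class CoefficientBand(BaseModel):
    lower: float = Field(ge=0)
    upper: float
    multiplier: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CoefficientBand":
        if not self.lower < self.upper:
            raise ValueError("band lower bound must be < upper bound")
        return self


class ScoreConfig(BaseModel):
    """Weights, coefficient bands and QC bounds, externalised so future
    re-weighting needs no code change."""

    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    trajectory_points: dict[TrajectoryGroup, float] = Field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORY_POINTS)
    )
    analytes: list[str] = Field(default_factory=lambda: list(DEFAULT_ANALYTES))
    min_observations: int = 5
    # analytes exempt from the minimum-observation rule: stool calprotectin
    # is accepted however sparse, since any abnormal result since diagnosis
    # still classifies the trajectory
    min_obs_exempt: list[str] = Field(default_factory=lambda: ["calprotectin"])
    normalization_window_years: float = 1.0
    coefficient_bands: list[CoefficientBand] = Field(
        default_factory=lambda: [
            CoefficientBand(lower=lo, upper=hi, multiplier=m)
            for lo, hi, m in DEFAULT_COEFFICIENT_BANDS
        ]
    )
    plausibility_bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_PLAUSIBILITY_BOUNDS)
    )
    sds_bounds: tuple[float, float] = DEFAULT_SDS_BOUNDS

    @model_validator(mode="after")
    def _check(self) -> "ScoreConfig":
        bands = self.coefficient_bands
        if not bands:
            raise ValueError("at least one coefficient band required")
        if bands[0].lower != 0.0:
            raise ValueError("coefficient bands must start at 0")
        for a, b in zip(bands, bands[1:]):
            if a.upper != b.lower:
                raise ValueError("coefficient bands must partition [0, inf) without gaps")
        if math.isfinite(bands[-1].upper):
            raise ValueError("last coefficient band must be unbounded above")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("default-profile weights must be >= 0")
        lo, hi = self.sds_bounds
        if not lo < hi:
            raise ValueError("sds_bounds must be ordered (low, high)")
        return self

    def blood_analytes(self) -> list[str]:
        return [a for a in self.analytes if a not in self.min_obs_exempt]

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        # inf is not valid YAML 1.1 across loaders; use .inf spelling via float repr
        for band in data["coefficient_bands"]:
            if band["upper"] is None or band["upper"] == float("inf"):
                band["upper"] = ".inf"
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        data = yaml.safe_load(Path(path).read_text())
        for band in data.get("coefficient_bands", []):
            if band.get("upper") in (".inf", "inf", None):
                band["upper"] = math.inf
        return cls.model_validate(data)


def default_config() -> ScoreConfig:
    return ScoreConfig()


#: Standard maximum of the default weight table (four named EIMs, no
#: "other autoimmune" category).
STANDARD_MAX_BASE = (
    3.0 * len(DEFAULT_ANALYTES)
    + sum(DEFAULT_WEIGHTS[k] for k in MED_CLASSES)
    + sum(DEFAULT_WEIGHTS[k] for k in COMPLICATIONS)
    + sum(DEFAULT_WEIGHTS[k] for k in SURGERIES)
    + sum(DEFAULT_WEIGHTS[k] for k in GROWTH_FLAGS)
    + sum(DEFAULT_WEIGHTS[k] for k in EIMS if k != "other_autoimmune")
)

__all__ = [
    "CoefficientBand",
    "ScoreConfig",
    "default_config",
    "DEFAULT_WEIGHTS",
    "DEFAULT_TRAJECTORY_POINTS",
    "DEFAULT_COEFFICIENT_BANDS",
    "DEFAULT_PLAUSIBILITY_BOUNDS",
    "DEFAULT_REFERENCE_INTERVALS",
    "DEFAULT_SDS_BOUNDS",
    "STANDARD_MAX_BASE",
]
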