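# Methods

## The index

The Pediatric Crohn Disease Morbidity Index (PCD-MI) is a composite,
longitudinal disease-burden score for pediatric Crohn disease. Unlike
single-timepoint activity indices (PCDAI, CDAI, HBI — out of scope here), it
summarises a patient's whole follow-up: the shape of their laboratory
trajectories, their cumulative therapy escalation, complicated disease
behaviour, surgery, growth failure, and extraintestinal manifestations
(EIMs). The score is

    PCD-MI = coefficient(followup_years) × Σ_c points(c)

over the components *c* of the weight table (`pcdmi.config.DEFAULT_WEIGHTS`):

| theme | components | points |
|---|---|---|
| laboratory trajectories | hemoglobin, CRP, platelets, albumin, fecal calprotectin | 0 / 1 / 3 each |
| medication (additive) | 5-ASA/topical 1; immunomodulator 2; first-line monoclonal 3; second-line monoclonal/small molecule 4 | up to 10 |
| complications | stricturing 3; fistulating 3 | up to 6 |
| surgery | intestinal resection 4; perianal procedure 2 | up to 6 |
| growth | weight flag 2; height flag 2 | up to 4 |
| EIMs | liver 3; skin 2; eye 2; arthritis 2; other autoimmune 2 | 9 named (+2) |

The standard maximum — all five series relapsing-remitting, all four
medication classes, both complications, both surgeries, both growth flags,
the four named EIM categories — is exactly 50 (15+10+6+6+4+9); a fifth EIM
category pushes an individual above 50 (to 52 with the defaults). With the
default coefficient table the adjusted maximum at under one year of
follow-up is 100.

The "other autoimmune comorbidity" weight is +2. Some printed renderings of
the table typeset this row with a leading minus; a negative weight is
inconsistent with both the stated overall maximum of 50 for four EIMs and
the possibility of exceeding 50 with a fifth, so the positive reading is the
only arithmetically coherent one. The weight table is configuration
(`ScoreConfig`, YAML round-trippable), so a future re-weighting needs no
code change.

## Trajectory classification

Each QC-passed patient-analyte series is reduced to abnormality flags
(value strictly outside the row's own age/sex-specific reference interval;
values exactly at a bound are normal, the standard laboratory convention)
and classified:

* **persistently normal** — no abnormal result at any time;
* **normalized** — at least one abnormal result, all abnormal results within
  the normalisation window (default 1.0 year after diagnosis), and no
  abnormal result after any normal one;
* **relapsing-remitting** — anything else: an abnormal result after the
  window, or a normal→abnormal recurrence even inside the window.

The recurrence convention was genuinely open: an oscillation confined to the
first year could be read as "normalised by one year". We classify it as
relapsing-remitting, because a documented relapse — whenever it occurs — is
the phenomenon the 3-point group exists to capture; only the window width is
configurable.

Patients followed for less than one window cannot show post-window
behaviour, so an end-state rule applies: relapsing-remitting if the last
result is abnormal (ongoing inflammation), normalized if normal after at
least one abnormal, persistently normal otherwise.

Series with fewer than 5 observations are `INSUFFICIENT_DATA` for the four
blood analytes. Fecal calprotectin is exempt: stool sampling is sparse in
routine care and any abnormal result since diagnosis still classifies the
trajectory, so calprotectin series of any length (≥1) are classified. An
insufficient series scores 0 but is marked `missing` in the result breakdown
(completeness is reportable); a patient whose *every* blood series is
insufficient is dropped from scoring entirely.

## Quality control

Laboratory rows carrying a sample-handling flag (hemolyzed, insufficient
sample, failed test, sample not received, clotted) or a value outside
per-analyte physiological plausibility bounds are rejected before
classification, each with exactly one primary reason (flags take precedence
over the plausibility check). The default bounds (hemoglobin 30–250 g/L,
CRP 0–500 mg/L, platelets 5–2000 ×10⁹/L, albumin 5–70 g/L, calprotectin
0–6000 µg/g, growth SDS ±5) are deliberately wide scaffolding choices of
this package, fully configurable, not clinical claims; site QC pipelines are
typically unpublished. Rows with no reference range at all are excluded
from abnormality classification with a warning rather than treated as
normal. No imputation or interpolation is performed.

## Phenotype keywords

Stricturing keywords: fibrosis, fibrotic, stricture, stricturing, narrowing,
narrowed, pre-stenotic dilatation, stenotic, reduced diameter. Fistulating:
fistulating, fistula, fistulae, fistulising, fistulizing, penetrating,
penetrate, penetrative, connection, connect, connecting. Matching is
case-insensitive on word boundaries; phrases tolerate hyphen/space
variation; the unambiguous clinical stems fistul- and strictur- match with
any suffix, while short generic words (connect, penetrate, …) match only as
whole words. The keyword pass is recall-oriented — its purpose is to
shortlist reports — and the curation override on each report
(confirmed/refuted) is the precision mechanism: a refuted verdict forces the
flag off regardless of matches, and wins over a conflicting confirmed
verdict from another report. Negation is deliberately not detected; negated
mentions are expected to be resolved by curation.

## Growth flags

Per dimension (height, weight), with baseline the earliest measure at or
after diagnosis, the flag triggers on the first satisfied rule of: (1) a
fall of strictly more than 1.0 SDS from baseline at any follow-up measure;
(2) a drop below −2.0 SDS during follow-up from a baseline at or above
−2.0; (3) no improvement (final ≤ baseline) from a baseline already below
−2.0. Rule 3 exempts children whose growth potential was already low from
the absolute threshold while still capturing persistent deficit.

## Follow-up coefficient

Scores accrued over short follow-up are upweighted so burdens are comparable
across durations. Default bands (half-open, `[lower, upper)` — so exactly
3.0 years falls in the ×1.25 band): <1 y ×2.0, 1–3 y ×1.5, 3–5 y ×1.25,
5–10 y ×1.1, ≥10 y ×1.0.

`derive_coefficients` re-derives the table from a scored cohort: per band,
factor = overall mean base score / band mean, then rescaled so the
longest-follow-up band equals 1.0 (equivalently: longest band's mean divided
by each band's mean), rounded to 2 decimals. Empty bands — typically the
<1-year band, since cohorts usually require ≥2 years of follow-up — are
filled by linear extension of the nearest derived factors on the band index;
linear extension is the simplest defensible extrapolation and is exposed as
such. Raw ratios are returned alongside for audit.

## Cohort statistics

`summarize` computes burden strata with inclusive thresholds (≤10 quiescent,
≥20 high burden, strictly between otherwise — inclusive so the three
proportions always partition the cohort), a left-closed histogram with bin
width 5 from 0, and per-diagnosis-year means. Normality uses the Lilliefors
variant of the Kolmogorov–Smirnov test (mean and SD estimated from the
sample; statsmodels implementation); reported p-values are capped at 0.2,
the classical table convention for this procedure, with the raw value also
returned. Between-year comparability uses one-way fixed-effects ANOVA
(`scipy.stats.f_oneway`).

## Synthetic cohorts

No pediatric Crohn EHR cohort is deposited publicly, so the test surface is
a generator (`pcdmi.synthetic_cohort`) whose outputs have known ground
truth. Defaults emulate a realistic single-centre cohort: 66 patients,
follow-up uniform on 2–10.5 years, diagnosis years 2012–2019, ~6 blood
results per patient-year (≥5 per analyte), sparse calprotectin (1 + Poisson
draws, mean ≈3 results) never normal at diagnosis, trajectory-group mixture
(0.45, 0.25, 0.30) for blood and (0, 0.45, 0.55) for calprotectin,
complication prevalences 10–15%, per-category EIM prevalences of 2–5%, and
growth-failure scenarios at ~16% combined. Values are drawn uniformly on
the required side of the reference interval but inside the plausibility
bounds — only the abnormality-flag pattern drives the score, so no
physiological realism (autocorrelation, treatment response, assay noise) is
attempted; passing end-to-end tests therefore demonstrates the pipeline's
arithmetic and rule fidelity, not robustness to messy real-world
measurement processes. Expected scores in the ground truth are computed by
direct summation over the intended assignments, independent of the scoring
module, so end-to-end recovery compares two routes to the same number.
`inject_qc_noise` appends flagged or implausible rows with a ledger; QC must
reject exactly the ledger.

## Numerical choices and degenerate inputs

Scores are kept at full precision internally; adjusted scores are rounded
to one decimal only on output. Band lookup is strict on positive follow-up.
Empty score lists, constant score vectors (normality), single diagnosis-year
groups (ANOVA), empty lab series (classification) and zero overall mean
(coefficient derivation) raise errors rather than returning sentinels.
Dates are converted to decimal years with 365.25-day years.

## Limitations

* The original development cohort is not available; cohort-specific
  statistics (its mean score, KS statistic, F statistic) are not
  reproduction targets.
* Component weights are pragmatic, inherited from prior activity-index
  practice, not effect estimates.
* Keyword phenotyping has no negation handling by design; precision relies
  on curation.
* SDS conversion from raw anthropometry is consumed, not performed; a
  national growth reference is required upstream.
* No endoscopic/histological severity components in this iteration.
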