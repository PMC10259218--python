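"""Keyword-based flagging of stricturing and fistulating disease.

Free-text endoscopy, MRI, ultrasound, CT and clinic-letter snippets are
searched for complicated-disease keywords.  The keyword pass is
deliberately recall-oriented — its role is to shortlist reports for
clinical review — and precision comes from the curation override fields
on each report: a clinician-set ``confirmed``/``refuted`` verdict always
replaces the keyword result.  Records with no keyword hit and no
override are recorded as non-stricturing / non-penetrating.

Matching rules:

* case-insensitive, on word boundaries;
* multi-word terms ("pre-stenotic dilatation", "reduced diameter")
  tolerate hyphen/space variation;
* unambiguous clinical stems (fistul-, strictur-) match with any suffix,
  so "fistulous" or "strictured" still hit; short generic words
  (connect, connection, penetrate, ...) match only as whole words to
  avoid e.g. "connect" firing inside "disconnected".

Negation ("no stricture seen") is NOT detected: such a report matches
and is expected to be resolved through curation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import ClinicalReport, Curation

# canonical keyword -> compiled pattern; ordered so that the evidence
# list reports the most specific listed term that matched
STRICTURING_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("pre-stenotic dilatation", re.compile(r"\bpre[\s-]?stenotic\s+dilatation\b", re.I)),
    ("reduced diameter", re.compile(r"\breduced\s+diameter\b", re.I)),
    ("stricturing", re.compile(r"\bstricturing\b", re.I)),
    ("stricture", re.compile(r"\bstricture\b", re.I)),
    ("strictur*", re.compile(r"\bstrictur\w+\b", re.I)),  # stem fallback
    ("stenotic", re.compile(r"\bstenotic\b", re.I)),
    ("fibrosis", re.compile(r"\bfibrosis\b", re.I)),
    ("fibrotic", re.compile(r"\bfibrotic\b", re.I)),
    ("narrowing", re.compile(r"\bnarrowing\b", re.I)),
    ("narrowed", re.compile(r"\bnarrowed\b", re.I)),
]

FISTULATING_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("fistulating", re.compile(r"\bfistulating\b", re.I)),
    ("fistulising", re.compile(r"\bfistulising\b", re.I)),
    ("fistulizing", re.compile(r"\bfistulizing\b", re.I)),
    ("fistulae", re.compile(r"\bfistulae\b", re.I)),
    ("fistula", re.compile(r"\bfistula\b", re.I)),
    ("fistul*", re.compile(r"\bfistul\w+\b", re.I)),  # stem fallback
    ("penetrating", re.compile(r"\bpenetrating\b", re.I)),
    ("penetrate", re.compile(r"\bpenetrate\b", re.I)),
    ("penetrative", re.compile(r"\bpenetrative\b", re.I)),
    ("connection", re.compile(r"\bconnection\b", re.I)),
    ("connecting", re.compile(r"\bconnecting\b", re.I)),
    ("connect", re.compile(r"\bconnect\b", re.I)),
]


def _match(text: str, patterns: Sequence[tuple[str, re.Pattern]]) -> set[str]:
    hits: set[str] = set()
    covered: list[tuple[int, int]] = []
    for name, pat in patterns:
        for m in pat.finditer(text):
            span = m.span()
            # spans inside an earlier, more specific match (phrases before
            # their constituent words, listed terms before stem fallbacks)
            # are already reported
            if any(a <= span[0] and span[1] <= b for a, b in covered):
                continue
            hits.add(name)
            covered.append(span)
    return hits


def match_keywords(text: str) -> dict[str, set[str]]:
    """Return the matched canonical keywords per category.

    Empty or missing text matches nothing.
    """
    text = text or ""
    return {
        "stricturing": _match(text, STRICTURING_PATTERNS),
        "fistulating": _match(text, FISTULATING_PATTERNS),
    }


@dataclass
class PhenotypeFlags:
    """Per-patient complicated-disease verdict with its audit trail.

    ``evidence`` holds (report index, matched keyword, source) triples;
    a True flag implies non-empty evidence unless a curated override set
    it.  A curated ``refuted`` forces the flag False regardless of
    keyword hits.
    """

    patient_id: str
    stricturing: bool = False
    fistulating: bool = False
    evidence: list[tuple[int, str, str]] = field(default_factory=list)
    overridden: dict[str, bool] = field(default_factory=dict)


def assign_phenotype(
    patient_id: str, reports: Iterable[ClinicalReport]
) -> PhenotypeFlags:
    """Combine keyword hits and curation overrides into patient flags.

    Overrides win over keyword verdicts; if multiple reports carry
    conflicting overrides for the same category, ``refuted`` wins (the
    clinician explicitly rejected the finding).  A patient with no
    reports gets both flags False.
    """
    flags = PhenotypeFlags(patient_id=patient_id)
    keyword_hit = {"stricturing": False, "fistulating": False}
    curation: dict[str, set[Curation]] = {"stricturing": set(), "fistulating": set()}

    for i, report in enumerate(reports):
        if report.patient_id != patient_id:
            raise ValueError(
                f"report for {report.patient_id!r} passed to patient {patient_id!r}"
            )
        matches = match_keywords(report.text)
        for category in ("stricturing", "fistulating"):
            for kw in sorted(matches[category]):
                flags.evidence.append((i, kw, report.source))
            if matches[category]:
                keyword_hit[category] = True
        curation["stricturing"].add(report.curated_stricturing)
        curation["fistulating"].add(report.curated_fistulating)

    verdict = {}
    for category in ("stricturing", "fistulating"):
        if Curation.REFUTED in curation[category]:
            verdict[category] = False
            flags.overridden[category] = True
        elif Curation.CONFIRMED in curation[category]:
            verdict[category] = True
            flags.overridden[category] = True
        else:
            verdict[category] = keyword_hit[category]
    flags.stricturing = verdict["stricturing"]
    flags.fistulating = verdict["fistulating"]
    return flags


def assign_cohort_phenotypes(
    reports: Sequence[ClinicalReport], patient_ids: Iterable[str]
) -> dict[str, PhenotypeFlags]:
    """Assign flags for every listed patient (absent reports => both False)."""
    by_patient: dict[str, list[ClinicalReport]] = {}
    for r in reports:
        by_patient.setdefault(r.patient_id, []).append(r)
    return {
        pid: assign_phenotype(pid, by_patient.get(pid, []))
        for pid in patient_ids
    }


__all__ = [
    "PhenotypeFlags",
    "match_keywords",
    "assign_phenotype",
    "assign_cohort_phenotypes",
    "STRICTURING_PATTERNS",
    "FISTULATING_PATTERNS",
]
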