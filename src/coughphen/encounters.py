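"""Cohort eligibility and derivation of deduplicated cough encounters.

A cough *encounter* is a dated, per-category event derived from one of:

* an NLP-positive cough mention in a provider note (``nlp_note``),
* an ICD-10 R05 diagnosis in an outpatient setting — ambulatory, day
  surgery, home visit, or urgent care (``diagnosis``),
* a written order for a cough-specific medication containing benzonatate
  or dextromethorphan, with guaifenesin expectorants, other mucoactive
  agents and codeine agents excluded (``medication_order``),
* in the claims-supplemented sensitivity mode, prescription-fill claims
  for the same medications and R05 outpatient claim diagnoses
  (``claim_fill`` / ``claim_diagnosis``).

EHR sources are deduplicated to at most one encounter per *category* per
day; claim sources to at most one per *person* per day.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    CATEGORY_ORDER,
    EncounterCategory,
    EncounterRecord,
    PatientRecord,
    normalize_code,
    parse_date,
)

logger = logging.getLogger(__name__)

#: Outpatient settings in which an R05 diagnosis counts as a cough encounter.
QUALIFYING_SETTINGS = frozenset({"ambulatory", "day_surgery", "home", "urgent_care"})

COUGH_CODE_PREFIX = "R05"

#: Ingredients whose presence marks ACE-inhibitor evidence in orders/fills.
ACE_INGREDIENTS = (
    "lisinopril", "enalapril", "ramipril", "benazepril", "captopril",
    "quinapril", "fosinopril", "perindopril", "trandolapril", "moexipril",
)


@dataclass(frozen=True)
class MedicationRule:
    """Cough-specific medication inclusion rule.

    An order qualifies iff it contains an included ingredient and no
    excluded one; combination products with any excluded ingredient
    (e.g. dextromethorphan-guaifenesin) are excluded because they are
    not specific to cough. Matching is case-insensitive substring over
    the drug name and ingredient fields.
    """

    include_ingredients: tuple[str, ...] = ("benzonatate", "dextromethorphan")
    exclude_ingredients: tuple[str, ...] = (
        "guaifenesin", "codeine", "acetylcysteine", "carbocisteine",
        "bromhexine", "ambroxol", "erdosteine",
    )

    def __post_init__(self) -> None:
        overlap = set(self.include_ingredients) & set(self.exclude_ingredients)
        if overlap:
            raise ValueError(f"include/exclude ingredient sets overlap: {sorted(overlap)}")

    def qualifies(self, *texts: str) -> bool:
        blob = " ".join(t.lower() for t in texts if t)
        if any(x in blob for x in self.exclude_ingredients):
            return False
        return any(i in blob for i in self.include_ingredients)


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility filters for the study cohort."""

    identification_start: _dt.date = _dt.date(2016, 1, 1)
    identification_end: _dt.date = _dt.date(2017, 3, 31)
    age_min: int = 18
    age_max: int = 85
    min_enrollment_months: int = 24
    exclude_ace_inhibitor: bool = True

    def __post_init__(self) -> None:
        if self.identification_start >= self.identification_end:
            raise ValueError("identification window start must precede end")


@dataclass
class CohortSelection:
    eligible: dict[str, _dt.date]  # patient_id -> index date
    exclusion_ledger: Counter = field(default_factory=Counter)
    excluded: dict[str, str] = field(default_factory=dict)  # patient_id -> reason


def _add_months(d: _dt.date, months: int) -> _dt.date:
    y, m = divmod(d.month - 1 + months, 12)
    # clamp to the target month's length (e.g. Jan 31 + 1mo -> Feb 28)
    last = [31, 29 if ((d.year + y) % 4 == 0 and ((d.year + y) % 100 != 0 or (d.year + y) % 400 == 0)) else 28,
            31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m]
    return _dt.date(d.year + y, m + 1, min(d.day, last))


def _merged_coverage_end(spans, start: _dt.date) -> Optional[_dt.date]:
    """Latest date continuously covered from `start` by spans merged
    across gaps of at most one day."""
    covered = None
    for s in sorted(spans, key=lambda s: s.start):
        if s.end < start and (covered is None):
            continue
        if covered is None:
            if s.start <= start <= s.end:
                covered = s.end
        elif s.start <= covered + _dt.timedelta(days=1):
            covered = max(covered, s.end)
        else:
            break
    return covered


def select_cohort(
    patients: Sequence[PatientRecord],
    spec: CohortSpec = CohortSpec(),
    orders: pd.DataFrame | None = None,
    claims: pd.DataFrame | None = None,
) -> CohortSelection:
    """Apply the eligibility filters and attribute exclusions.

    A patient is eligible iff: an enrollment span overlaps the
    identification window (the earliest enrollment date inside the
    window is the index date); age at index year within bounds;
    continuous enrollment for the minimum months from the index date;
    and no ACE-inhibitor evidence (patient flag, written order, or fill
    claim). Exclusions use first-failing-rule attribution, in the order
    enrollment -> age -> ACE.
    """
    ace_patients: set[str] = set()
    if orders is not None and len(orders):
        blob = (orders["drug_name"].str.lower() + " " + orders["ingredient"].str.lower())
        mask = blob.apply(lambda t: any(a in t for a in ACE_INGREDIENTS))
        ace_patients |= set(orders.loc[mask, "patient_id"])
    if claims is not None and len(claims):
        fills = claims[claims["kind"] == "fill"]
        if len(fills):
            mask = fills["code_or_ingredient"].str.lower().apply(
                lambda t: any(a in t for a in ACE_INGREDIENTS)
            )
            ace_patients |= set(fills.loc[mask, "patient_id"])

    sel = CohortSelection(eligible={})
    for p in patients:
        index_date = None
        for s in sorted(p.enrollment_spans, key=lambda s: s.start):
            if s.end >= spec.identification_start and s.start <= spec.identification_end:
                index_date = max(s.start, spec.identification_start)
                break
        if index_date is None:
            sel.exclusion_ledger["enrollment"] += 1
            sel.excluded[p.patient_id] = "enrollment"
            continue
        covered = _merged_coverage_end(p.enrollment_spans, index_date)
        required_end = _add_months(index_date, spec.min_enrollment_months) - _dt.timedelta(days=1)
        if covered is None or covered < required_end:
            sel.exclusion_ledger["enrollment"] += 1
            sel.excluded[p.patient_id] = "enrollment"
            continue
        age = index_date.year - p.birth_year
        if not (spec.age_min <= age <= spec.age_max):
            sel.exclusion_ledger["age"] += 1
            sel.excluded[p.patient_id] = "age"
            continue
        if spec.exclude_ace_inhibitor and (
            p.ace_inhibitor_flag or p.patient_id in ace_patients
        ):
            sel.exclusion_ledger["ace_inhibitor"] += 1
            sel.excluded[p.patient_id] = "ace_inhibitor"
            continue
        p.index_date = index_date
        sel.eligible[p.patient_id] = index_date
    return sel


# ---------------------------------------------------------- derivations

def _dedup(records: Iterable[EncounterRecord]) -> list[EncounterRecord]:
    """One record per (patient, date, category); first source wins."""
    seen: dict[tuple, EncounterRecord] = {}
    for r in records:
        seen.setdefault((r.patient_id, r.date, r.category), r)
    return sorted(seen.values(), key=EncounterRecord.sort_key)


def notes_to_encounters(classified_mentions: pd.DataFrame) -> list[EncounterRecord]:
    """NLP_NOTE encounters from POSITIVE mentions, one per patient-day.

    Expects the classified-mention table (columns patient_id, note_date,
    note_id, label).
    """
    recs = []
    for row in classified_mentions.itertuples(index=False):
        if row.label != "POSITIVE":
            continue
        recs.append(
            EncounterRecord(
                patient_id=row.patient_id,
                date=parse_date(row.note_date),
                category=EncounterCategory.NLP_NOTE,
                source_id=str(row.note_id),
            )
        )
    return _dedup(recs)


def diagnoses_to_encounters(diagnoses: pd.DataFrame) -> list[EncounterRecord]:
    """DIAGNOSIS encounters: R05 (and children, by prefix) in qualifying
    outpatient settings, one per patient-day."""
    recs = []
    for row in diagnoses.itertuples(index=False):
        if not normalize_code(row.code).startswith(COUGH_CODE_PREFIX):
            continue
        if row.setting not in QUALIFYING_SETTINGS:
            continue
        recs.append(
            EncounterRecord(
                patient_id=row.patient_id,
                date=parse_date(row.date),
                category=EncounterCategory.DIAGNOSIS,
                source_id=f"dx:{row.code}:{row.setting}",
            )
        )
    return _dedup(recs)


def medications_to_encounters(
    orders: pd.DataFrame, rule: MedicationRule = MedicationRule()
) -> list[EncounterRecord]:
    """MEDICATION_ORDER encounters for qualifying cough medications."""
    recs = []
    for row in orders.itertuples(index=False):
        if not rule.qualifies(row.drug_name, row.ingredient):
            continue
        recs.append(
            EncounterRecord(
                patient_id=row.patient_id,
                date=parse_date(row.date),
                category=EncounterCategory.MEDICATION_ORDER,
                source_id=f"rx:{row.drug_name}",
            )
        )
    return _dedup(recs)


def claims_to_encounters(
    claims: pd.DataFrame, rule: MedicationRule = MedicationRule()
) -> list[EncounterRecord]:
    """Claim encounters for the sensitivity mode: qualifying fills and
    R05 outpatient claim diagnoses, collapsed to one per *person* per
    day regardless of claim kind (diagnosis wins a same-day tie for the
    recorded category)."""
    candidates: list[EncounterRecord] = []
    for row in claims.itertuples(index=False):
        date = parse_date(row.date)
        if row.kind == "fill":
            if rule.qualifies(row.code_or_ingredient):
                candidates.append(
                    EncounterRecord(row.patient_id, date, EncounterCategory.CLAIM_FILL,
                                    f"claim_fill:{row.code_or_ingredient}")
                )
        elif row.kind == "diagnosis":
            if normalize_code(row.code_or_ingredient).startswith(COUGH_CODE_PREFIX):
                candidates.append(
                    EncounterRecord(row.patient_id, date, EncounterCategory.CLAIM_DIAGNOSIS,
                                    f"claim_dx:{row.code_or_ingredient}")
                )
    # one per person-day: keep the lowest-ordered category
    best: dict[tuple, EncounterRecord] = {}
    for r in candidates:
        key = (r.patient_id, r.date)
        cur = best.get(key)
        if cur is None or CATEGORY_ORDER[r.category] < CATEGORY_ORDER[cur.category]:
            best[key] = r
    return sorted(best.values(), key=EncounterRecord.sort_key)


def build_encounters(
    classified_mentions: pd.DataFrame | None = None,
    diagnoses: pd.DataFrame | None = None,
    orders: pd.DataFrame | None = None,
    claims: pd.DataFrame | None = None,
    rule: MedicationRule = MedicationRule(),
) -> list[EncounterRecord]:
    """Union of encounters across every supplied source family."""
    out: list[EncounterRecord] = []
    if classified_mentions is not None and len(classified_mentions):
        out += notes_to_encounters(classified_mentions)
    if diagnoses is not None and len(diagnoses):
        out += diagnoses_to_encounters(diagnoses)
    if orders is not None and len(orders):
        out += medications_to_encounters(orders, rule)
    if claims is not None and len(claims):
        out += claims_to_encounters(claims, rule)
    return sorted(out, key=EncounterRecord.sort_key)
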