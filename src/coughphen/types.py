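"""Core domain types for chronic-cough phenotyping.

The pipeline moves through a small set of records: free-text provider
notes, character-offset annotations over them, classified cough mentions,
dated cough encounters, and per-patient chronic-cough determinations.
Everything here is a plain frozen dataclass or enum so records hash,
compare, and round-trip through the text formats in :mod:`coughphen.io`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class ContextLabel(str, Enum):
    """Semantic status of a cough mention in its note context.

    POSITIVE means the cough is affirmed for the patient: the mention is
    relevant to the patient and its context is neither negated nor
    hypothetical nor about someone else. Temporality is deliberately not
    modelled — a historical cough mention is classified as current.
    """

    POSITIVE = "POSITIVE"
    NEGATED = "NEGATED"
    HYPOTHETICAL = "HYPOTHETICAL"
    NOT_PATIENT = "NOT_PATIENT"
    OTHER = "OTHER"


class EncounterCategory(str, Enum):
    """Provenance category of a cough encounter.

    CLAIM_* categories exist only in the claims-supplemented sensitivity
    mode; the default pipeline uses the three EHR categories.
    """

    NLP_NOTE = "nlp_note"
    DIAGNOSIS = "diagnosis"
    MEDICATION_ORDER = "medication_order"
    CLAIM_DIAGNOSIS = "claim_diagnosis"
    CLAIM_FILL = "claim_fill"


#: Categories available without claims supplementation.
EHR_CATEGORIES = frozenset(
    {EncounterCategory.NLP_NOTE, EncounterCategory.DIAGNOSIS, EncounterCategory.MEDICATION_ORDER}
)
CLAIM_CATEGORIES = frozenset({EncounterCategory.CLAIM_DIAGNOSIS, EncounterCategory.CLAIM_FILL})

#: Deterministic ordering used for same-day tie-breaks.
CATEGORY_ORDER = {
    EncounterCategory.NLP_NOTE: 0,
    EncounterCategory.DIAGNOSIS: 1,
    EncounterCategory.MEDICATION_ORDER: 2,
    EncounterCategory.CLAIM_DIAGNOSIS: 3,
    EncounterCategory.CLAIM_FILL: 4,
}


@dataclass(frozen=True)
class ProviderNote:
    note_id: str
    patient_id: str
    note_date: _dt.date
    text: str


@dataclass(frozen=True)
class AnnotationSpan:
    """A gold-standard label over a character span of a note.

    Offsets are 0-based half-open: ``text[start:end]`` is the annotated
    surface string.
    """

    note_id: str
    start: int
    end: int
    label: ContextLabel
    annotator_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets ({self.start}, {self.end})")


@dataclass(frozen=True)
class MentionCandidate:
    """A lexicon match in a note, before context classification."""

    note_id: str
    start: int
    end: int
    surface: str
    term: str


@dataclass(frozen=True)
class ClassifiedMention:
    note_id: str
    start: int
    end: int
    surface: str
    term: str
    label: ContextLabel
    score: float
    method: str  # "rules" | "model"


@dataclass(frozen=True)
class EncounterRecord:
    """A dated, deduplicated cough event — the phenotyping substrate."""

    patient_id: str
    date: _dt.date
    category: EncounterCategory
    source_id: str = ""

    def sort_key(self) -> tuple:
        return (self.patient_id, self.date, CATEGORY_ORDER[self.category])


@dataclass(frozen=True)
class EnrollmentSpan:
    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"enrollment span start {self.start} after end {self.end}")


@dataclass
class PatientRecord:
    patient_id: str
    birth_year: int
    sex: str
    region: str
    enrollment_spans: list[EnrollmentSpan] = field(default_factory=list)
    ace_inhibitor_flag: bool = False
    index_date: Optional[_dt.date] = None


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN(/TN) counts. TN is absent for entity-level evaluation,
    where true negatives are not enumerable."""

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        counts = [self.tp, self.fp, self.fn] + ([] if self.tn is None else [self.tn])
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")


@dataclass
class CCResult:
    """Per-patient chronic-cough determination.

    ``is_cc`` is true iff an eligibility date exists; the eligibility
    date is the date of the k-th encounter of the earliest qualifying
    set, and ``gap_days`` is its distance from the first qualifying
    encounter.
    """

    patient_id: str
    is_cc: bool
    eligibility_date: Optional[_dt.date] = None
    qualifying_encounters: list[EncounterRecord] = field(default_factory=list)
    total_encounters: int = 0

    @property
    def gap_days(self) -> Optional[int]:
        if not self.is_cc or not self.qualifying_encounters:
            return None
        return (self.qualifying_encounters[-1].date - self.qualifying_encounters[0].date).days

    @property
    def attribution(self) -> Optional[str]:
        """'nlp_only' / 'structured_only' / 'combination' over the
        qualifying encounters' categories; None when not CC."""
        if not self.is_cc:
            return None
        cats = {e.category for e in self.qualifying_encounters}
        has_nlp = EncounterCategory.NLP_NOTE in cats
        has_structured = bool(cats - {EncounterCategory.NLP_NOTE})
        if has_nlp and has_structured:
            return "combination"
        return "nlp_only" if has_nlp else "structured_only"


def parse_date(value) -> _dt.date:
    """Parse an ISO-8601 calendar date; passes through date objects."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value).strip())


def normalize_code(code: str) -> str:
    """Normalize a diagnosis code for comparison: uppercase, strip the
    decimal point and surrounding whitespace ('r05.' -> 'R05')."""
    return str(code).strip().upper().replace(".", "")
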