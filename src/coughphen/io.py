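"""Readers and writers for the pipeline's text formats.

Formats are deliberately plain and diff-able:

* notes — JSON-lines, one note per line with keys
  ``note_id, patient_id, note_date, text``
* annotations — TSV with header ``note_id, start, end, label, annotator_id``
* diagnoses — CSV ``patient_id, date, code_system, code, setting``
* medication orders — CSV ``patient_id, date, drug_name, ingredient``
* claims — CSV ``patient_id, date, kind, code_or_ingredient``
* patients — CSV ``patient_id, birth_year, sex, region, enroll_start,
  enroll_end, ace_inhibitor`` (one row per enrollment span)
* encounters — CSV ``patient_id, date, category, source_id``

Validation is total: every malformed record raises (or is reported) with
its line number; nothing is silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AnnotationSpan,
    CATEGORY_ORDER,
    ClassifiedMention,
    ContextLabel,
    EncounterCategory,
    EncounterRecord,
    EnrollmentSpan,
    PatientRecord,
    ProviderNote,
    normalize_code,
    parse_date,
)


class DataValidationError(ValueError):
    """A malformed input record; the message names the file line."""


NOTE_KEYS = ("note_id", "patient_id", "note_date", "text")

DIAGNOSIS_COLUMNS = ["patient_id", "date", "code_system", "code", "setting"]
ORDER_COLUMNS = ["patient_id", "date", "drug_name", "ingredient"]
CLAIM_COLUMNS = ["patient_id", "date", "kind", "code_or_ingredient"]
PATIENT_COLUMNS = [
    "patient_id", "birth_year", "sex", "region", "enroll_start", "enroll_end", "ace_inhibitor",
]

VALID_SETTINGS = {"ambulatory", "day_surgery", "home", "urgent_care", "inpatient", "er", "other"}


# ---------------------------------------------------------------- notes

def read_notes(path) -> list[ProviderNote]:
    notes: list[ProviderNote] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DataValidationError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            missing = [k for k in NOTE_KEYS if k not in rec]
            if missing:
                raise DataValidationError(
                    f"{path}:{lineno}: missing key(s) {', '.join(missing)}"
                )
            try:
                date = parse_date(rec["note_date"])
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}:{lineno}: bad note_date {rec['note_date']!r}"
                ) from exc
            note_id = str(rec["note_id"])
            if note_id in seen:
                raise DataValidationError(f"{path}:{lineno}: duplicate note_id {note_id!r}")
            seen.add(note_id)
            notes.append(
                ProviderNote(
                    note_id=note_id,
                    patient_id=str(rec["patient_id"]),
                    note_date=date,
                    text=str(rec["text"]),
                )
            )
    return notes


def write_notes(notes: Iterable[ProviderNote], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "note_date": n.note_date.isoformat(),
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ----------------------------------------------------------- annotations

def read_annotations(
    path,
    corpus: Sequence[ProviderNote] | None = None,
    lexicon: Sequence[str] | None = None,
) -> list[AnnotationSpan]:
    """Read standoff annotations; when ``corpus`` is given, validate
    offsets against note lengths and (when ``lexicon`` is given) flag
    spans whose substring contains no lexicon term.
    """
    notes_by_id = {n.note_id: n for n in corpus} if corpus is not None else None
    spans: list[AnnotationSpan] = []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["note_id", "start", "end", "label", "annotator_id"]
    if list(df.columns) != expected:
        raise DataValidationError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
            label = ContextLabel(row.label)
        except (ValueError, KeyError) as exc:
            raise DataValidationError(f"{path}:{i}: {exc}") from exc
        if notes_by_id is not None:
            note = notes_by_id.get(row.note_id)
            if note is None:
                raise DataValidationError(f"{path}:{i}: unknown note_id {row.note_id!r}")
            if not (0 <= start < end <= len(note.text)):
                raise DataValidationError(
                    f"{path}:{i}: span ({start}, {end}) out of range for note "
                    f"{row.note_id!r} of length {len(note.text)}"
                )
            if lexicon is not None:
                surface = note.text[start:end].lower()
                if not any(term.lower() in surface for term in lexicon):
                    import warnings

                    warnings.warn(
                        f"{path}:{i}: span contains no lexicon term: {surface!r}",
                        stacklevel=2,
                    )
        spans.append(AnnotationSpan(row.note_id, start, end, label, row.annotator_id))
    return spans


def write_annotations(spans: Iterable[AnnotationSpan], path) -> None:
    rows = [
        {"note_id": s.note_id, "start": s.start, "end": s.end,
         "label": s.label.value, "annotator_id": s.annotator_id}
        for s in spans
    ]
    pd.DataFrame(rows, columns=["note_id", "start", "end", "label", "annotator_id"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------ event tables

_SCHEMAS = {
    "diagnosis": DIAGNOSIS_COLUMNS,
    "medication_order": ORDER_COLUMNS,
    "claim": CLAIM_COLUMNS,
}


def read_event_table(path, schema: str) -> pd.DataFrame:
    """Read a diagnosis / medication-order / claims CSV.

    Dates are parsed to ``datetime.date``; diagnosis and claim codes are
    normalized (uppercase, decimal point stripped) for ICD-10 comparison.
    """
    if schema not in _SCHEMAS:
        raise DataValidationError(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}"
        )
    expected = _SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected:
        raise DataValidationError(
            f"{path}: schema {schema!r} expects columns {expected}, got {list(df.columns)}"
        )
    try:
        df["date"] = df["date"].map(parse_date)
    except ValueError as exc:
        raise DataValidationError(f"{path}: unparseable date ({exc})") from exc
    if schema == "diagnosis":
        df["code"] = df["code"].map(normalize_code)
        bad = ~df["setting"].isin(VALID_SETTINGS)
        if bad.any():
            first = df.index[bad][0] + 2
            raise DataValidationError(
                f"{path}:{first}: setting must be one of {sorted(VALID_SETTINGS)}"
            )
    elif schema == "claim":
        bad = ~df["kind"].isin({"fill", "diagnosis"})
        if bad.any():
            first = df.index[bad][0] + 2
            raise DataValidationError(f"{path}:{first}: claim kind must be fill or diagnosis")
        is_dx = df["kind"] == "diagnosis"
        df.loc[is_dx, "code_or_ingredient"] = df.loc[is_dx, "code_or_ingredient"].map(
            normalize_code
        )
    return df


def write_event_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "date" in out.columns:
        out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


# --------------------------------------------------------------- patients

def read_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PATIENT_COLUMNS:
        raise DataValidationError(
            f"{path}: expected columns {PATIENT_COLUMNS}, got {list(df.columns)}"
        )
    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            span = EnrollmentSpan(parse_date(row.enroll_start), parse_date(row.enroll_end))
            birth_year = int(row.birth_year)
            ace = bool(int(row.ace_inhibitor))
        except ValueError as exc:
            raise DataValidationError(f"{path}:{i}: {exc}") from exc
        rec = patients.get(row.patient_id)
        if rec is None:
            rec = PatientRecord(
                patient_id=row.patient_id,
                birth_year=birth_year,
                sex=row.sex,
                region=row.region,
                ace_inhibitor_flag=ace,
            )
            patients[row.patient_id] = rec
        rec.ace_inhibitor_flag = rec.ace_inhibitor_flag or ace
        rec.enrollment_spans.append(span)
    for rec in patients.values():
        rec.enrollment_spans.sort(key=lambda s: s.start)
        for a, b in zip(rec.enrollment_spans, rec.enrollment_spans[1:]):
            if b.start <= a.end:
                raise DataValidationError(
                    f"patient {rec.patient_id}: overlapping enrollment spans"
                )
    return list(patients.values())


def write_patients(patients: Iterable[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        spans = p.enrollment_spans or [None]
        for s in spans:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "birth_year": p.birth_year,
                    "sex": p.sex,
                    "region": p.region,
                    "enroll_start": s.start.isoformat() if s else "",
                    "enroll_end": s.end.isoformat() if s else "",
                    "ace_inhibitor": int(p.ace_inhibitor_flag),
                }
            )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


# -------------------------------------------------------------- encounters

def write_encounters(encounters: Iterable[EncounterRecord], path) -> None:
    recs = sorted(encounters, key=EncounterRecord.sort_key)
    rows = [
        {"patient_id": e.patient_id, "date": e.date.isoformat(),
         "category": e.category.value, "source_id": e.source_id}
        for e in recs
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", "category", "source_id"]).to_csv(
        path, index=False
    )


def read_encounters(path) -> list[EncounterRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["patient_id", "date", "category", "source_id"]
    if list(df.columns) != expected:
        raise DataValidationError(f"{path}: expected columns {expected}")
    return [
        EncounterRecord(
            patient_id=r.patient_id,
            date=parse_date(r.date),
            category=EncounterCategory(r.category),
            source_id=r.source_id,
        )
        for r in df.itertuples(index=False)
    ]


# ----------------------------------------------------- classified mentions

def write_classified_mentions(
    mentions: Iterable[tuple[ProviderNote, ClassifiedMention]], path
) -> None:
    """Write mentions with their note's patient/date context as TSV."""
    rows = [
        {
            "note_id": m.note_id,
            "patient_id": note.patient_id,
            "note_date": note.note_date.isoformat(),
            "start": m.start,
            "end": m.end,
            "term": m.term,
            "label": m.label.value,
            "score": m.score,
            "method": m.method,
        }
        for note, m in mentions
    ]
    cols = ["note_id", "patient_id", "note_date", "start", "end", "term", "label", "score", "method"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_classified_mentions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["note_date"] = df["note_date"].map(parse_date)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def write_cc_results(results, path) -> None:
    """Results CSV: one row per patient with CC flag, eligibility date,
    encounter count, gap, and attribution class."""
    rows = [
        {
            "patient_id": r.patient_id,
            "is_cc": int(r.is_cc),
            "eligibility_date": r.eligibility_date.isoformat() if r.eligibility_date else "",
            "n_encounters": r.total_encounters,
            "gap_days": r.gap_days if r.gap_days is not None else "",
            "attribution": r.attribution or "",
        }
        for r in results
    ]
    cols = ["patient_id", "is_cc", "eligibility_date", "n_encounters", "gap_days", "attribution"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
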