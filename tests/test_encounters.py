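"""Encounter derivation and cohort eligibility filters."""

import datetime as dt

import pandas as pd
import pytest

from coughphen import (
    CohortSpec,
    MedicationRule,
    claims_to_encounters,
    diagnoses_to_encounters,
    medications_to_encounters,
    notes_to_encounters,
    select_cohort,
)
from coughphen.types import EncounterCategory


def dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "code_system", "code", "setting"])


D = dt.date


@pytest.mark.parametrize(
    "code, setting, n",
    [
        ("R05", "urgent_care", 1),
        ("R05", "ambulatory", 1),
        ("r05.", "home", 1),          # normalization
        ("R05.1", "day_surgery", 1),  # child code matches by prefix
        ("R05", "inpatient", 0),      # setting filter
        ("R05", "er", 0),
        ("J45.9", "ambulatory", 0),   # code filter
    ],
)
def test_diagnosis_filters(code, setting, n):
    recs = diagnoses_to_encounters(dx([("p1", D(2016, 2, 1), "ICD-10-CM", code, setting)]))
    assert len(recs) == n
    if n:
        assert recs[0].category == EncounterCategory.DIAGNOSIS


@pytest.mark.parametrize(
    "drug, ingredient, n",
    [
        ("benzonatate 100mg", "benzonatate", 1),
        ("Dextromethorphan HBr", "dextromethorphan", 1),
        ("dextromethorphan-guaifenesin", "dextromethorphan-guaifenesin", 0),  # combination excluded
        ("guaifenesin 600mg", "guaifenesin", 0),
        ("codeine/promethazine", "codeine-promethazine", 0),
        ("lisinopril 10mg", "lisinopril", 0),  # unrecognized -> skipped, not fatal
    ],
)
def test_medication_rule(drug, ingredient, n):
    orders = pd.DataFrame(
        [("p1", D(2016, 2, 1), drug, ingredient)],
        columns=["patient_id", "date", "drug_name", "ingredient"],
    )
    assert len(medications_to_encounters(orders)) == n


def test_medication_rule_rejects_overlapping_sets():
    with pytest.raises(ValueError, match="overlap"):
        MedicationRule(include_ingredients=("benzonatate",),
                       exclude_ingredients=("benzonatate",))


def test_positive_mentions_collapse_to_one_per_day():
    mentions = pd.DataFrame(
        [
            {"patient_id": "p1", "note_date": D(2016, 3, 1), "note_id": "n1", "label": "POSITIVE"},
            {"patient_id": "p1", "note_date": D(2016, 3, 1), "note_id": "n1", "label": "POSITIVE"},
            {"patient_id": "p1", "note_date": D(2016, 3, 1), "note_id": "n2", "label": "POSITIVE"},
            {"patient_id": "p1", "note_date": D(2016, 3, 2), "note_id": "n3", "label": "NEGATED"},
        ]
    )
    recs = notes_to_encounters(mentions)
    assert len(recs) == 1
    assert recs[0].date == D(2016, 3, 1)


def test_claims_one_per_person_per_day():
    claims = pd.DataFrame(
        [
            ("p1", D(2016, 4, 1), "fill", "benzonatate"),
            ("p1", D(2016, 4, 1), "diagnosis", "R05"),   # same day -> one encounter
            ("p1", D(2016, 4, 2), "fill", "guaifenesin"),  # excluded medication
            ("p1", D(2016, 4, 3), "diagnosis", "J20.9"),   # non-cough code
        ],
        columns=["patient_id", "date", "kind", "code_or_ingredient"],
    )
    recs = claims_to_encounters(claims)
    assert len(recs) == 1
    assert recs[0].date == D(2016, 4, 1)


def test_dedup_is_idempotent_and_conservative(population):
    recs = diagnoses_to_encounters(population.diagnoses)
    again = diagnoses_to_encounters(population.diagnoses)
    assert recs == again
    assert len(recs) <= len(population.diagnoses)
    assert all(r.source_id for r in recs)


def test_union_partition_sums(population):
    """Per-category encounter sets partition the union; every encounter
    comes from exactly one category after per-category dedup."""
    from coughphen import build_encounters

    parts = [
        diagnoses_to_encounters(population.diagnoses),
        medications_to_encounters(population.orders),
        claims_to_encounters(population.claims),
    ]
    union = build_encounters(None, population.diagnoses,
                             population.orders, population.claims)
    assert sum(len(p) for p in parts) == len(union)


def test_cohort_selection_examples():
    from coughphen.types import EnrollmentSpan, PatientRecord

    spec = CohortSpec()
    ok_span = [EnrollmentSpan(D(2016, 1, 1), D(2018, 6, 30))]
    young = PatientRecord("young", 1999, "F", "West", list(ok_span))   # 17 in 2016
    ace = PatientRecord("ace", 1970, "M", "South", list(ok_span), ace_inhibitor_flag=True)
    short = PatientRecord("short", 1970, "F", "West",
                          [EnrollmentSpan(D(2016, 1, 1), D(2016, 12, 31))])
    none = PatientRecord("nospan", 1970, "F", "West", [])
    good = PatientRecord("good", 1950, "F", "Midwest", list(ok_span))
    sel = select_cohort([young, ace, short, none, good], spec)
    assert set(sel.eligible) == {"good"}
    assert sel.eligible["good"] == D(2016, 1, 1)
    assert sel.excluded == {"young": "age", "ace": "ace_inhibitor",
                            "short": "enrollment", "nospan": "enrollment"}


def test_ace_fill_claim_excludes_patient():
    from coughphen.types import EnrollmentSpan, PatientRecord

    p = PatientRecord("p1", 1960, "M", "South",
                      [EnrollmentSpan(D(2016, 1, 1), D(2018, 6, 30))])
    claims = pd.DataFrame([("p1", D(2016, 5, 1), "fill", "lisinopril 10mg")],
                          columns=["patient_id", "date", "kind", "code_or_ingredient"])
    sel = select_cohort([p], CohortSpec(), claims=claims)
    assert sel.excluded == {"p1": "ace_inhibitor"}


def test_exclusion_ledger_matches_generator_manifest(population):
    sel = select_cohort(population.patients, CohortSpec(),
                        orders=population.orders, claims=population.claims)
    planted = population.manifest["exclusion_counts"]
    assert dict(sel.exclusion_ledger) == {
        "ace_inhibitor": planted["ace"],
        "age": planted["age"],
        "enrollment": planted["enrollment"],
    }
    assert len(sel.eligible) == population.manifest["n_eligible"]
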