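"""The temporal chronic-cough rule against a brute-force subset oracle."""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coughphen import CCParameters, eligibility_histogram, find_cc, gap_statistics, run_cohort
from coughphen.types import EncounterCategory, EncounterRecord

BASE = dt.date(2016, 1, 1)


def timeline(days, category=EncounterCategory.NLP_NOTE, pid="p1"):
    return [EncounterRecord(pid, BASE + dt.timedelta(days=int(d)), category) for d in days]


def oracle(days, params=CCParameters()):
    """Exhaustive search over all k-subsets: qualifies iff some subset's
    span lies in [span_min, window]; eligibility is the earliest subset
    maximum. Independent of the production sliding-window scan."""
    dates = sorted(BASE + dt.timedelta(days=int(d)) for d in days)
    best = None
    for combo in itertools.combinations(dates, params.k_min):
        span = (combo[-1] - combo[0]).days
        if params.span_min_days <= span <= params.window_days:
            best = combo[-1] if best is None else min(best, combo[-1])
    return best is not None, best


@pytest.mark.parametrize(
    "days, is_cc, elig_day",
    [
        ([0, 30, 70], True, 70),          # span 70 in [56, 120]
        ([0, 10, 40], False, None),       # max span 40 < 56
        ([0, 100, 130, 160], True, 160),  # {0,100,130} spans 130 > 120
        ([], False, None),
        ([0, 56], False, None),           # only two encounters
        ([0, 1, 56], True, 56),           # boundary span exactly 56
        ([0, 1, 120], True, 120),         # boundary span exactly 120
        ([0, 1, 121], False, None),       # just over the window
        ([0, 1, 55], False, None),        # just under the spacing
    ],
)
def test_worked_examples(days, is_cc, elig_day):
    res = find_cc(timeline(days))
    assert res.is_cc == is_cc
    expected = BASE + dt.timedelta(days=elig_day) if elig_day is not None else None
    assert res.eligibility_date == expected
    # cross-check each example against the exhaustive oracle
    assert (res.is_cc, res.eligibility_date) == oracle(days)


def test_oracle_equivalence_random_timelines():
    """Sliding-window scan agrees with exhaustive subset search on both
    the CC decision and the eligibility date."""
    rng = np.random.default_rng(17)
    for _ in range(2000):
        n = int(rng.integers(0, 16))
        days = sorted(set(rng.integers(0, 400, size=n).tolist()))
        res = find_cc(timeline(days))
        assert (res.is_cc, res.eligibility_date) == oracle(days)


@given(st.lists(st.integers(0, 400), min_size=0, max_size=15),
       st.integers(0, 400))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_adding_an_encounter_is_monotone(days, extra):
    """Adding an encounter never un-qualifies a patient and never moves
    the eligibility date later."""
    before = find_cc(timeline(days))
    after = find_cc(timeline(days + [extra]))
    if before.is_cc:
        assert after.is_cc
        assert after.eligibility_date <= before.eligibility_date


def test_unsorted_input_is_sorted_internally():
    res = find_cc(timeline([70, 0, 30]))
    assert res.is_cc and res.eligibility_date == BASE + dt.timedelta(days=70)


def test_qualifying_set_and_gap_bounds():
    res = find_cc(timeline([0, 5, 30, 70, 90]))
    assert len(res.qualifying_encounters) == 3
    assert res.total_encounters == 5
    assert 56 <= res.gap_days <= 120
    # minimality: no subset has an earlier k-th date
    assert res.eligibility_date == oracle([0, 5, 30, 70, 90])[1]


def test_collapse_same_day_counts_distinct_days():
    recs = timeline([0, 60], EncounterCategory.NLP_NOTE) + timeline(
        [0], EncounterCategory.DIAGNOSIS
    )
    assert find_cc(recs).is_cc  # three distinct records, span 60
    assert not find_cc(recs, CCParameters(collapse_same_day=True)).is_cc


def test_run_cohort_modes_and_attribution(population):
    from coughphen import build_encounters, classify_corpus, select_cohort
    from coughphen.encounters import CohortSpec
    import pandas as pd

    classified = classify_corpus(population.notes, "rules")
    mentions = pd.DataFrame(
        [{"patient_id": n.patient_id, "note_date": n.note_date,
          "note_id": m.note_id, "label": m.label.value} for n, m in classified]
    )
    encs = build_encounters(mentions, population.diagnoses,
                            population.orders, population.claims)
    sel = select_cohort(population.patients, CohortSpec(),
                        orders=population.orders, claims=population.claims)
    enrollment = {p.patient_id: p.enrollment_spans for p in population.patients}
    ids = sorted(sel.eligible)
    ehr, s1 = run_cohort(encs, mode="ehr_only", cohort_ids=ids, enrollment=enrollment)
    both, s2 = run_cohort(encs, mode="ehr_plus_claims", cohort_ids=ids, enrollment=enrollment)

    cc_ehr = {r.patient_id for r in ehr if r.is_cc}
    cc_both = {r.patient_id for r in both if r.is_cc}
    assert cc_both >= cc_ehr  # claims mode is a superset

    man = population.manifest["patients"]
    assert cc_ehr == {pid for pid, e in man.items() if e["true_cc"]}
    assert cc_both - cc_ehr == {pid for pid, e in man.items() if e["claims_only_cc"]}
    for r in ehr:
        if r.is_cc:
            assert r.attribution == man[r.patient_id]["attribution"]
            assert r.eligibility_date.isoformat() == man[r.patient_id]["eligibility_date"]
    assert s1["n_cc"] == len(cc_ehr)
    assert s2["cohort_size"] == len(ids)
    assert sum(s1["attribution"].values()) == s1["n_cc"]


def test_cohort_with_too_few_encounters_has_no_cc():
    encs = timeline([0, 60], pid="a") + timeline([10], pid="b")
    results, summary = run_cohort(encs)
    assert summary["n_cc"] == 0 and all(not r.is_cc for r in results)


def test_eligibility_histogram_conserves_and_empty():
    assert eligibility_histogram([]).empty
    res = [find_cc(timeline([0, 30, 70], pid=f"p{i}")) for i in range(5)]
    hist = eligibility_histogram(res)
    assert int(hist.sum()) == 5


def test_histogram_peaks_in_planted_season():
    """Winter-peaked generator seasonality shows up as a winter peak in
    the month-of-year distribution of eligibility dates (sign check,
    sized so the seasonal contrast dominates sampling noise)."""
    from coughphen.synth import SimConfig, gen_population

    pop = gen_population(SimConfig(seed=29, n_patients=8000, n_notes=10,
                                   split_sizes=(6, 2, 2)))
    results = []
    for pid, e in pop.manifest["patients"].items():
        if e["true_cc"]:
            recs = [EncounterRecord(pid, dt.date.fromisoformat(d), EncounterCategory(c))
                    for d, c in e["encounters"]]
            results.append(find_cc(recs))
    hist = eligibility_histogram(results)
    assert int(hist.sum()) == len(results)
    by_month = np.zeros(12)
    for period, count in hist.items():
        by_month[period.month - 1] += count
    winter = by_month[[11, 0, 1]].sum()   # Dec, Jan, Feb
    summer = by_month[[5, 6, 7]].sum()    # Jun, Jul, Aug
    assert winter > summer


def test_gap_statistics():
    assert gap_statistics([]) is None
    one = [find_cc(timeline([0, 30, 70]))]
    s = gap_statistics(one)
    assert s == {"n": 1, "mean": 70.0, "sd": 0.0, "min": 70.0, "max": 70.0}
    same = [find_cc(timeline([0, 10, 60], pid=f"p{i}")) for i in range(4)]
    assert gap_statistics(same)["sd"] == 0.0


def test_parameter_validation():
    with pytest.raises(ValueError):
        CCParameters(k_min=1)
    with pytest.raises(ValueError):
        CCParameters(span_min_days=200, window_days=120)
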