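"""Demographics, comorbidity grouping, and PPPM aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from coughphen.characterize import (
    CodeGrouper,
    comorbidity_prevalence,
    pppm_summary,
    summarize_demographics,
)
from coughphen.types import CCResult, EnrollmentSpan, PatientRecord

D = dt.date


def cc(pid):
    return CCResult(patient_id=pid, is_cc=True, eligibility_date=D(2016, 6, 1))


def patient(pid, birth_year, sex="F", region="West"):
    return PatientRecord(pid, birth_year, sex, region,
                         [EnrollmentSpan(D(2016, 1, 1), D(2018, 1, 1))],
                         index_date=D(2016, 1, 1))


def test_single_patient_demographics():
    table = summarize_demographics([patient("p1", 1946)], [cc("p1")])
    t = table.set_index(["characteristic", "level"])
    assert t.loc[("age_group", ">=65"), "pct"] == 100.0
    assert t.loc[("sex", "F"), "pct"] == 100.0


def test_demographics_recover_planted_mix_and_sum(population):
    from coughphen import CohortSpec, select_cohort

    sel = select_cohort(population.patients, CohortSpec())
    man = population.manifest["patients"]
    cc_results = [cc(pid) for pid, e in man.items() if e["true_cc"]]
    for p in population.patients:
        p.index_date = sel.eligible.get(p.patient_id)
    table = summarize_demographics(population.patients, cc_results)
    age = table[table.characteristic == "age_group"]
    assert age.n.sum() == len(cc_results)          # bands partition the cohort
    assert age.pct.sum() == pytest.approx(100.0, abs=0.5)
    sex = table[table.characteristic == "sex"].set_index("level")
    expected_f = sum(
        1 for p in population.patients
        if p.patient_id in {r.patient_id for r in cc_results} and p.sex == "F"
    )
    assert sex.loc["F", "n"] == expected_f


def test_grouper_longest_prefix_and_unmapped():
    g = CodeGrouper({"R05": "other lower respiratory disease",
                     "R0982": "respiratory infections",
                     "R09": "other symptoms"})
    assert g.categorize("r05.") == "other lower respiratory disease"
    assert g.categorize("R0982") == "respiratory infections"   # longest prefix wins
    assert g.categorize("R091") == "other symptoms"
    assert g.categorize("Z99") == "unmapped"


def test_comorbidity_prevalence_counts_patient_once_per_category():
    g = CodeGrouper({"R05": "resp"})
    dx = pd.DataFrame(
        [("p1", D(2016, 2, 1), "ICD-10-CM", "R05", "ambulatory"),
         ("p1", D(2016, 3, 1), "ICD-10-CM", "R05", "ambulatory"),
         ("p1", D(2016, 3, 2), "ICD-10-CM", "Z99", "ambulatory")],
        columns=["patient_id", "date", "code_system", "code", "setting"],
    )
    table = comorbidity_prevalence(dx, g, [cc("p1")]).set_index("category")
    assert table.loc["resp", "pct"] == 100.0
    assert table.loc["unmapped", "n"] == 1  # unmapped bucket, not dropped


def util_df(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "channel", "cost", "inpatient_days"])


def test_pppm_arithmetic_single_patient():
    """$2400 over 24 months is $100 PPPM; annualized x12."""
    u = util_df([("p1", D(2016, 5, 1), "office", 2400.0, 0)])
    table = pppm_summary(u, [cc("p1")], months=24).set_index("channel")
    assert table.loc["office", "pppm_cost_mean"] == pytest.approx(100.0)
    assert table.loc["total", "pppm_cost_mean"] * 12 == pytest.approx(1200.0)


def test_total_decomposes_into_medical_plus_pharmacy():
    u = util_df([
        ("p1", D(2016, 5, 1), "office", 240.0, 0),
        ("p1", D(2016, 6, 1), "pharmacy", 120.0, 0),
        ("p2", D(2016, 7, 1), "er", 480.0, 0),
    ])
    t = pppm_summary(u, [cc("p1"), cc("p2")], months=24).set_index("channel")
    assert t.loc["total", "pppm_cost_mean"] == pytest.approx(
        t.loc["medical", "pppm_cost_mean"] + t.loc["pharmacy", "pppm_cost_mean"]
    )


def test_inflation_factors_scale_by_calendar_year():
    u = util_df([("p1", D(2016, 5, 1), "office", 100.0, 0),
                 ("p1", D(2017, 5, 1), "office", 100.0, 0)])
    t = pppm_summary(u, [cc("p1")], months=2, inflation_factors={2016: 1.1}).set_index("channel")
    assert t.loc["office", "pppm_cost_mean"] == pytest.approx((110.0 + 100.0) / 2)


def test_negative_cost_rejected():
    u = util_df([("p1", D(2016, 5, 1), "office", -5.0, 0)])
    with pytest.raises(ValueError, match="negative cost"):
        pppm_summary(u, [cc("p1")])


def test_generated_utilization_recovers_planted_rates():
    from coughphen.synth import gen_utilization

    rates = {"office": 1.0, "pharmacy": 3.0, "er": 0.1,
             "hospital_outpatient": 0.5, "inpatient": 0.02, "other_medical": 0.2}
    costs = {k: 100.0 for k in rates}
    index_dates = {f"p{i:03d}": D(2016, 1, 1) for i in range(300)}
    u = gen_utilization(index_dates, months=24, seed=1, pppm_rates=rates, event_costs=costs)
    t = pppm_summary(u, [cc(p) for p in index_dates], months=24).set_index("channel")
    for ch in ("office", "pharmacy"):
        se = np.sqrt(rates[ch] / (24 * 300))  # Poisson Monte-Carlo error
        assert abs(t.loc[ch, "pppm_count_mean"] - rates[ch]) < 4 * se


def test_any_use_percentage_monotone_in_threshold():
    rng = np.random.default_rng(2)
    rows = [("p%02d" % i, D(2016, 3, 1), "office", 10.0, 0)
            for i in range(20) for _ in range(rng.integers(0, 5))]
    u = util_df(rows)
    counts = u.groupby("patient_id").size().reindex(
        [f"p{i:02d}" for i in range(20)], fill_value=0)
    pcts = [(counts >= k).mean() for k in range(1, 5)]
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))
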