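"""Descriptive characterization of the chronic-cough cohort.

Demographics by age band / sex / region, comorbidity prevalence through
a user-supplied diagnosis-code grouper (a prefix -> category table in
the spirit of AHRQ's CCSR, which is not redistributable here), and
per-patient-per-month (PPPM) health-care resource use and cost
aggregation with per-calendar-year inflation adjustment.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CCResult, PatientRecord, normalize_code

AGE_BANDS = [
    ("18-39", 18, 39),
    ("40-44", 40, 44),
    ("45-49", 45, 49),
    ("50-54", 50, 54),
    ("55-59", 55, 59),
    ("60-64", 60, 64),
    (">=65", 65, 200),
]

UTILIZATION_CHANNELS = (
    "office", "hospital_outpatient", "er", "inpatient", "pharmacy", "other_medical",
)
MEDICAL_CHANNELS = ("office", "hospital_outpatient", "er", "inpatient", "other_medical")


def age_band(age: int) -> Optional[str]:
    for name, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return name
    return None


def summarize_demographics(
    patients: Sequence[PatientRecord], cc_results: Sequence[CCResult]
) -> pd.DataFrame:
    """Counts and percentages (1 dp) by age band, sex, and region for
    the CC subset. Ages are taken at the index year."""
    cc_ids = {r.patient_id for r in cc_results if r.is_cc}
    subset = [p for p in patients if p.patient_id in cc_ids]
    n = len(subset)
    rows = []

    def add(group, level, count):
        rows.append({
            "characteristic": group, "level": level, "n": count,
            "pct": round(100.0 * count / n, 1) if n else float("nan"),
        })

    bands = {name: 0 for name, _, _ in AGE_BANDS}
    for p in subset:
        year = p.index_date.year if p.index_date else (
            p.enrollment_spans[0].start.year if p.enrollment_spans else _dt.date.today().year
        )
        b = age_band(year - p.birth_year)
        if b:
            bands[b] += 1
    for name, _, _ in AGE_BANDS:
        add("age_group", name, bands[name])
    for sex in sorted({p.sex for p in subset}):
        add("sex", sex, sum(p.sex == sex for p in subset))
    for region in sorted({p.region for p in subset}):
        add("region", region, sum(p.region == region for p in subset))
    return pd.DataFrame(rows, columns=["characteristic", "level", "n", "pct"])


@dataclass
class CodeGrouper:
    """Longest-prefix mapping from diagnosis codes to clinical
    categories; unmapped codes land in the 'unmapped' bucket."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {normalize_code(k): v for k, v in self.mapping.items()}

    @classmethod
    def from_csv(cls, path) -> "CodeGrouper":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(df.columns) != ["prefix", "category"]:
            raise ValueError(f"{path}: grouper needs columns ['prefix', 'category']")
        return cls(dict(zip(df["prefix"], df["category"])))

    def categorize(self, code: str) -> str:
        norm = normalize_code(code)
        for length in range(len(norm), 0, -1):
            cat = self.mapping.get(norm[:length])
            if cat is not None:
                return cat
        return "unmapped"


def comorbidity_prevalence(
    diagnoses: pd.DataFrame,
    grouper: CodeGrouper,
    cc_results: Sequence[CCResult],
    observation_window: Optional[tuple[_dt.date, _dt.date]] = None,
) -> pd.DataFrame:
    """Percentage of CC patients with >= 1 code in each category during
    the window; a patient counts once per category."""
    cc_ids = {r.patient_id for r in cc_results if r.is_cc}
    n = len(cc_ids)
    seen: dict[str, set[str]] = {}
    for row in diagnoses.itertuples(index=False):
        if row.patient_id not in cc_ids:
            continue
        if observation_window is not None:
            if not (observation_window[0] <= row.date <= observation_window[1]):
                continue
        cat = grouper.categorize(row.code)
        seen.setdefault(cat, set()).add(row.patient_id)
    rows = [
        {"category": cat, "n": len(pids),
         "pct": round(100.0 * len(pids) / n, 1) if n else float("nan")}
        for cat, pids in sorted(seen.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "n", "pct"])


def pppm_summary(
    utilization: pd.DataFrame,
    cc_results: Sequence[CCResult],
    months: float = 24.0,
    inflation_factors: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Per-channel PPPM counts and costs over the CC cohort.

    ``utilization`` columns: patient_id, date, channel, cost,
    inpatient_days. Per patient, PPPM = (sum of inflation-adjusted
    amounts) / months; the table reports cohort mean (SD, n-1) of PPPM
    counts and costs per channel, any-use N (%), the ambulatory roll-up
    (office + hospital outpatient), the medical roll-up, and the total
    (medical + pharmacy, summed per patient before averaging). Negative
    costs are rejected.
    """
    if months <= 0:
        raise ValueError("months must be positive")
    if (utilization["cost"].astype(float) < 0).any():
        bad = utilization.index[utilization["cost"].astype(float) < 0][0]
        raise ValueError(f"negative cost at utilization row {bad}")
    factors = dict(inflation_factors or {})
    cc_ids = sorted({r.patient_id for r in cc_results if r.is_cc})
    n = len(cc_ids)
    idx = {pid: i for i, pid in enumerate(cc_ids)}

    channels = list(UTILIZATION_CHANNELS)
    count_mat = np.zeros((n, len(channels)))
    cost_mat = np.zeros((n, len(channels)))
    inpatient_days = np.zeros(n)
    for row in utilization.itertuples(index=False):
        i = idx.get(row.patient_id)
        if i is None:
            continue
        j = channels.index(row.channel)
        year = row.date.year if hasattr(row.date, "year") else int(str(row.date)[:4])
        adj = float(row.cost) * factors.get(year, 1.0)
        count_mat[i, j] += 1
        cost_mat[i, j] += adj
        if row.channel == "inpatient":
            inpatient_days[i] += int(row.inpatient_days or 0)

    def _sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    rows = []

    def add(name, counts_pp, costs_pp, any_use=None):
        rows.append({
            "channel": name,
            "n_any_use": int(any_use.sum()) if any_use is not None else None,
            "pct_any_use": round(100.0 * any_use.mean(), 1) if any_use is not None and n else None,
            "pppm_count_mean": float(np.mean(counts_pp)) if counts_pp is not None else None,
            "pppm_count_sd": _sd(counts_pp) if counts_pp is not None else None,
            "pppm_cost_mean": float(np.mean(costs_pp)),
            "pppm_cost_sd": _sd(costs_pp),
        })

    if n == 0:
        return pd.DataFrame(rows)
    per_month_counts = count_mat / months
    per_month_costs = cost_mat / months
    for j, ch in enumerate(channels):
        add(ch, per_month_counts[:, j], per_month_costs[:, j], any_use=count_mat[:, j] > 0)
    amb_idx = [channels.index("office"), channels.index("hospital_outpatient")]
    add("ambulatory", per_month_counts[:, amb_idx].sum(axis=1),
        per_month_costs[:, amb_idx].sum(axis=1), any_use=count_mat[:, amb_idx].sum(axis=1) > 0)
    med_idx = [channels.index(c) for c in MEDICAL_CHANNELS]
    add("medical", None, per_month_costs[:, med_idx].sum(axis=1))
    add("total", None, per_month_costs.sum(axis=1))
    out = pd.DataFrame(rows)
    out.attrs["mean_inpatient_days"] = (
        float(inpatient_days[count_mat[:, channels.index("inpatient")] > 0].mean())
        if (count_mat[:, channels.index("inpatient")] > 0).any() else None
    )
    return out
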