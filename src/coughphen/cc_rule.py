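"""The chronic-cough temporal rule.

A patient has chronic cough (CC) when at least ``k_min`` cough
encounters fall within a ``window_days``-day period and the first and
last of those qualifying encounters are at least ``span_min_days``
apart. With the defaults (3, 56, 120) this operationalizes the clinical
definition of CC — daily cough for eight weeks or more — on encounter
timelines. The *eligibility date* is the date of the k-th encounter of
the earliest qualifying set.

``find_cc`` runs a single chronological pass: because intermediate
encounters of a candidate set always lie between its first and last
dates, a qualifying set exists ending at encounter *j* iff some
encounter *i* with at least ``k_min - 2`` encounters between them
satisfies ``span_min_days <= d_j - d_i <= window_days``. Scanning *j*
in date order therefore finds the earliest eligibility date in O(n).
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CCResult,
    CLAIM_CATEGORIES,
    EncounterRecord,
    EnrollmentSpan,
)


@dataclass(frozen=True)
class CCParameters:
    k_min: int = 3
    span_min_days: int = 56
    window_days: int = 120
    collapse_same_day: bool = False

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if not (0 < self.span_min_days <= self.window_days):
            raise ValueError("require 0 < span_min_days <= window_days")


def find_cc(
    timeline: Sequence[EncounterRecord], params: CCParameters = CCParameters()
) -> CCResult:
    """Decide CC status for one patient's deduplicated timeline.

    Day differences are inclusive integer date differences:
    "within 120 days" is ``d_last - d_first <= 120`` and the spacing
    requirement is ``d_last - d_first >= 56``. With
    ``collapse_same_day`` set, same-day encounters of different
    categories count as a single encounter; by default they are
    distinct (the span requirement already forbids same-day-only
    qualification).
    """
    recs = sorted(timeline, key=EncounterRecord.sort_key)
    total = len(recs)
    pid = recs[0].patient_id if recs else ""
    if params.collapse_same_day:
        seen: dict[_dt.date, EncounterRecord] = {}
        for r in recs:
            seen.setdefault(r.date, r)
        recs = sorted(seen.values(), key=EncounterRecord.sort_key)
    n = len(recs)
    k = params.k_min
    lo = 0
    for j in range(k - 1, n):
        dj = recs[j].date
        while (dj - recs[lo].date).days > params.window_days:
            lo += 1
        if lo <= j - k + 1 and (dj - recs[lo].date).days >= params.span_min_days:
            qualifying = [recs[lo]] + recs[lo + 1: lo + k - 1] + [recs[j]]
            return CCResult(
                patient_id=pid,
                is_cc=True,
                eligibility_date=dj,
                qualifying_encounters=qualifying,
                total_encounters=total,
            )
    return CCResult(patient_id=pid, is_cc=False, total_encounters=total)


def run_cohort(
    encounters: Iterable[EncounterRecord],
    params: CCParameters = CCParameters(),
    mode: str = "ehr_only",
    cohort_ids: Optional[Iterable[str]] = None,
    enrollment: Optional[dict[str, list[EnrollmentSpan]]] = None,
) -> tuple[list[CCResult], dict]:
    """Apply the CC rule per patient and summarize attribution.

    ``mode`` is ``ehr_only`` (claim categories dropped) or
    ``ehr_plus_claims``. When ``cohort_ids`` is given, results cover
    exactly those patients (patients with no encounters included as
    non-CC) and prevalence uses the cohort size as denominator. When
    ``enrollment`` is given, encounters outside a patient's enrollment
    spans are dropped (counted in the summary).
    """
    if mode not in {"ehr_only", "ehr_plus_claims"}:
        raise ValueError("mode must be ehr_only or ehr_plus_claims")
    dropped_enrollment = 0
    by_patient: dict[str, list[EncounterRecord]] = {}
    for e in encounters:
        if mode == "ehr_only" and e.category in CLAIM_CATEGORIES:
            continue
        if enrollment is not None:
            spans = enrollment.get(e.patient_id, [])
            if not any(s.start <= e.date <= s.end for s in spans):
                dropped_enrollment += 1
                continue
        by_patient.setdefault(e.patient_id, []).append(e)

    ids = list(cohort_ids) if cohort_ids is not None else sorted(by_patient)
    results = []
    for pid in ids:
        tl = by_patient.get(pid, [])
        res = find_cc(tl, params) if tl else CCResult(patient_id=pid, is_cc=False)
        res.patient_id = pid
        results.append(res)

    attribution = Counter(r.attribution for r in results if r.is_cc)
    n_cc = sum(r.is_cc for r in results)
    summary = {
        "mode": mode,
        "cohort_size": len(ids),
        "n_cc": n_cc,
        "prevalence": n_cc / len(ids) if ids else float("nan"),
        "attribution": dict(attribution),
        "dropped_outside_enrollment": dropped_enrollment,
        "total_encounters": sum(len(v) for v in by_patient.values()),
    }
    return results, summary


def eligibility_histogram(cc_results: Iterable[CCResult]) -> pd.Series:
    """Counts of eligibility dates per calendar month; the total equals
    the number of CC patients. Empty for a cohort with no CC."""
    dates = [r.eligibility_date for r in cc_results if r.is_cc]
    if not dates:
        return pd.Series(dtype=int)
    idx = pd.PeriodIndex([pd.Period(d, freq="M") for d in dates], freq="M")
    counts = pd.Series(1, index=idx).groupby(level=0).sum()
    full = pd.period_range(counts.index.min(), counts.index.max(), freq="M")
    return counts.reindex(full, fill_value=0).astype(int)


def gap_statistics(cc_results: Iterable[CCResult]) -> Optional[dict]:
    """Mean and SD of the first-to-last qualifying-encounter gap (days)
    over CC patients; None when there are no CC patients. SD uses n-1
    (0.0 for a single patient)."""
    gaps = [r.gap_days for r in cc_results if r.is_cc and r.gap_days is not None]
    if not gaps:
        return None
    arr = np.asarray(gaps, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return {"n": len(arr), "mean": float(arr.mean()), "sd": sd,
            "min": float(arr.min()), "max": float(arr.max())}
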