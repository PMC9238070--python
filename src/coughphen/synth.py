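"""Seeded synthetic-EHR generator with ground-truth manifests.

Every input family the pipeline consumes can be generated here with the
truth planted and recorded: annotated note corpora (exact mention
offsets and context labels, an optional second annotator with a
configurable disagreement rate), patient populations with planted
eligibility exclusions, encounter streams in which chronic-cough
patients satisfy the (k, span, window) rule *by construction* and
non-CC patients provably violate it, claims that expand the CC set by a
planted amount, and utilization/cost records with known per-channel
rates.

Note text is template-based so that character offsets are exact; the
template bank is built from the trigger lexicon, and each planted
mention is checked against the rules engine at generation time so that
a noiseless run of the pipeline recovers the manifest exactly. Planted
CC / non-CC encounter sets are verified against a brute-force subset
oracle (not the production sliding-window scan) to avoid
self-fulfilling bugs.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cc_rule import CCParameters
from .nlp import classify_context_rules, default_triggers, extract_mentions, TriggerLexicon
from .types import (
    AnnotationSpan,
    ContextLabel,
    EncounterCategory,
    EnrollmentSpan,
    PatientRecord,
    ProviderNote,
)

# ---------------------------------------------------------------- config

DEFAULT_LABEL_MIXTURE = {
    ContextLabel.POSITIVE: 0.55,
    ContextLabel.NEGATED: 0.25,
    ContextLabel.HYPOTHETICAL: 0.10,
    ContextLabel.NOT_PATIENT: 0.05,
    ContextLabel.OTHER: 0.05,
}

DEFAULT_ATTRIBUTION_MIXTURE = {"nlp_only": 0.37, "structured_only": 0.16, "combination": 0.47}

DEFAULT_AGE_BAND_MIXTURE = {
    (18, 39): 0.105, (40, 44): 0.043, (45, 49): 0.067, (50, 54): 0.090,
    (55, 59): 0.105, (60, 64): 0.104, (65, 85): 0.486,
}

DEFAULT_REGION_MIXTURE = {"Northeast": 0.141, "Midwest": 0.477, "South": 0.283, "West": 0.099}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate the study design the pipeline targets: a 1000-note
    annotation corpus split 600/200/200, an identification window of
    Jan 2016 - Mar 2017 with a 24-month observation period, a planted
    chronic-cough prevalence of 1.5% with a further 1.2% reachable only
    through claims, winter-peaked seasonality, and exclusion fractions
    for ACE-inhibitor use, age, and enrollment gaps.
    """

    seed: int = 0
    # corpus
    n_notes: int = 1000
    split_sizes: tuple[int, int, int] = (600, 200, 200)
    label_mixture: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MIXTURE))
    mentions_per_note: tuple[int, int] = (1, 3)
    disagreement_rate: float = 0.0
    # population
    n_patients: int = 10_000
    cc_fraction: float = 0.015
    claims_only_cc_fraction: float = 0.012
    ace_fraction: float = 0.10
    age_ineligible_fraction: float = 0.05
    enrollment_gap_fraction: float = 0.05
    background_encounter_rate: float = 0.5  # mean encounters per non-CC patient
    extra_cc_encounter_rate: float = 1.0    # mean post-eligibility extras per CC patient
    distractor_rate: float = 0.10           # fraction of patients given non-qualifying records
    seasonal_amplitude: float = 0.6
    seasonal_phase_month: int = 1           # month of peak encounter rate
    attribution_mixture: dict = field(default_factory=lambda: dict(DEFAULT_ATTRIBUTION_MIXTURE))
    age_band_mixture: dict = field(default_factory=lambda: dict(DEFAULT_AGE_BAND_MIXTURE))
    female_fraction: float = 0.667
    region_mixture: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIXTURE))
    identification_start: _dt.date = _dt.date(2016, 1, 1)
    identification_end: _dt.date = _dt.date(2017, 3, 31)
    observation_months: int = 24
    cc_params: CCParameters = field(default_factory=CCParameters)

    def __post_init__(self) -> None:
        for name, mix in (
            ("label_mixture", self.label_mixture),
            ("attribution_mixture", self.attribution_mixture),
            ("age_band_mixture", self.age_band_mixture),
            ("region_mixture", self.region_mixture),
        ):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has a negative proportion")
        for name in ("cc_fraction", "claims_only_cc_fraction", "ace_fraction",
                     "age_ineligible_fraction", "enrollment_gap_fraction",
                     "disagreement_rate", "background_encounter_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if sum(self.split_sizes) != self.n_notes:
            raise ValueError("split_sizes must sum to n_notes")


# ------------------------------------------------------------- templates

#: Sentence templates per label; {term} is replaced by a lexicon term.
#: Built around the default trigger lexicon so the rules engine labels
#: each planted mention exactly as intended (checked at generation time).
TEMPLATES = {
    ContextLabel.POSITIVE: [
        "Patient reports {term} at night.",
        "Persistent {term} for the past two weeks.",
        "Presents with {term} and mild congestion.",
        "Worsening {term} since the last visit.",
        "History of {term} x 5 weeks improving.",
        "Dry {term} noted on exam.",
    ],
    ContextLabel.NEGATED: [
        "Patient denies {term} today.",
        "No {term}, no fever.",
        "Lungs clear, without {term}.",
        "Negative for {term} and wheeze.",
        "Denies any {term} or dyspnea.",
    ],
    ContextLabel.HYPOTHETICAL: [
        "Medication may cause {term}.",
        "Return if {term} develops.",
        "Discussed risk of {term} with this therapy.",
        "Watch for {term} over the coming week.",
    ],
    ContextLabel.NOT_PATIENT: [
        "Mother has chronic {term}.",
        "Family history of {term} reported.",
        "Wife has {term} at home.",
    ],
    ContextLabel.OTHER: [
        "Reviewed {term} etiquette.",
        "Completed {term} questionnaire.",
        "Provided handout on {term} today.",
    ],
}

FILLER_SENTENCES = [
    "Vitals stable.",
    "Blood pressure 120/80.",
    "Medication list reviewed.",
    "Follow up in two weeks.",
    "Patient resting comfortably.",
    "Lungs clear to auscultation.",
    "Reviewed labs from last visit.",
    "Dr. Coughlan to follow.",
]

TERMS = ("cough", "coughing", "coughs", "coughed", "cougher", "tussis")


def _check_template_bank(triggers: TriggerLexicon) -> None:
    """Every template, instantiated, must be labelled as intended by
    the rules engine; fillers must contain no lexicon term."""
    for label, templates in TEMPLATES.items():
        for tpl in templates:
            text = tpl.format(term="cough")
            note = ProviderNote("chk", "chk", _dt.date(2016, 1, 1), text)
            mentions = extract_mentions(note)
            if len(mentions) != 1:
                raise RuntimeError(f"template {tpl!r} plants {len(mentions)} mentions")
            got = classify_context_rules(note, mentions[0], triggers).label
            if got != label:
                raise RuntimeError(f"template {tpl!r}: rules give {got}, expected {label}")
    for s in FILLER_SENTENCES:
        if extract_mentions(ProviderNote("chk", "chk", _dt.date(2016, 1, 1), s)):
            raise RuntimeError(f"filler sentence contains a lexicon term: {s!r}")


def _build_note_text(rng, labels: Sequence[ContextLabel]):
    """Compose a note from filler + one template sentence per requested
    label; returns (text, [(start, end, term, label)])."""
    pieces: list[tuple[str, Optional[tuple]]] = []
    for lab in labels:
        tpl = TEMPLATES[lab][rng.integers(len(TEMPLATES[lab]))]
        term = TERMS[rng.integers(len(TERMS))]
        prefix = tpl.split("{term}")[0]
        sent = tpl.format(term=term)
        pieces.append((sent, (len(prefix), len(prefix) + len(term), term, lab)))
    for _ in range(int(rng.integers(1, 4))):
        pieces.append((FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))], None))
    rng.shuffle(pieces)
    text_parts, planted, pos = [], [], 0
    for sent, info in pieces:
        if info is not None:
            s, e, term, lab = info
            planted.append((pos + s, pos + e, term, lab))
        text_parts.append(sent)
        pos += len(sent) + 1  # single space joiner
    return " ".join(text_parts), planted


# ---------------------------------------------------------------- corpus

@dataclass
class CorpusBundle:
    notes: list[ProviderNote]
    gold: list[AnnotationSpan]                # adjudicated labels
    annotator_spans: list[AnnotationSpan]     # two independent channels
    splits: dict[str, list[str]]              # train/val/test note ids
    manifest: dict


def gen_corpus(config: SimConfig, triggers: TriggerLexicon | None = None) -> CorpusBundle:
    """Generate an annotated note corpus with exact planted offsets.

    Gold labels are the adjudicated truth (annotator id
    ``adjudicated``); two synthetic annotator channels are emitted, the
    second disagreeing with the first at ``disagreement_rate`` per
    mention (flipped to a random different label).
    """
    triggers = triggers or default_triggers()
    _check_template_bank(triggers)
    rng = np.random.default_rng(config.seed)
    labels_all = list(config.label_mixture)
    probs = np.array([config.label_mixture[l] for l in labels_all], dtype=float)
    probs = probs / probs.sum()
    all_labels = [l for l in ContextLabel]

    notes, gold, ann = [], [], []
    manifest_notes = []
    label_counts: dict[str, int] = {}
    start_date = config.identification_start
    horizon = (config.identification_end - start_date).days
    for i in range(config.n_notes):
        note_id = f"N{i:05d}"
        k = int(rng.integers(config.mentions_per_note[0], config.mentions_per_note[1] + 1))
        labs = [labels_all[j] for j in rng.choice(len(labels_all), size=k, p=probs)]
        text, planted = _build_note_text(rng, labs)
        date = start_date + _dt.timedelta(days=int(rng.integers(0, horizon + 1)))
        note = ProviderNote(note_id, f"CP{i:05d}", date, text)
        notes.append(note)
        mentions_manifest = []
        for s, e, term, lab in planted:
            gold.append(AnnotationSpan(note_id, s, e, lab, "adjudicated"))
            ann.append(AnnotationSpan(note_id, s, e, lab, "ann1"))
            lab2 = lab
            if rng.random() < config.disagreement_rate:
                others = [l for l in all_labels if l != lab]
                lab2 = others[rng.integers(len(others))]
            ann.append(AnnotationSpan(note_id, s, e, lab2, "ann2"))
            mentions_manifest.append(
                {"start": s, "end": e, "term": term, "label": lab.value}
            )
            label_counts[lab.value] = label_counts.get(lab.value, 0) + 1
        manifest_notes.append({"note_id": note_id, "mentions": mentions_manifest})

    ids = [n.note_id for n in notes]
    n_tr, n_va, n_te = config.split_sizes
    perm = rng.permutation(len(ids))
    splits = {
        "train": [ids[j] for j in perm[:n_tr]],
        "val": [ids[j] for j in perm[n_tr: n_tr + n_va]],
        "test": [ids[j] for j in perm[n_tr + n_va:]],
    }
    manifest = {
        "seed": config.seed,
        "n_notes": config.n_notes,
        "label_counts": label_counts,
        "notes": manifest_notes,
        "splits": splits,
    }
    return CorpusBundle(notes=notes, gold=gold, annotator_spans=ann,
                        splits=splits, manifest=manifest)


# ------------------------------------------------------------ population

def brute_force_cc(dates: Sequence[_dt.date], params: CCParameters):
    """Exhaustive subset oracle: earliest eligibility date over all
    k-subsets with span within [span_min, window], or (False, None).

    Used to certify generated timelines; deliberately independent of
    the production sliding-window scan.
    """
    dates = sorted(dates)
    best = None
    for combo in itertools.combinations(dates, params.k_min):
        span = (combo[-1] - combo[0]).days
        if params.span_min_days <= span <= params.window_days:
            if best is None or combo[-1] < best:
                best = combo[-1]
    return (best is not None), best


@dataclass
class PopulationBundle:
    patients: list[PatientRecord]
    notes: list[ProviderNote]
    diagnoses: pd.DataFrame
    orders: pd.DataFrame
    claims: pd.DataFrame
    manifest: dict


_QUALIFYING_SETTINGS = ("ambulatory", "day_surgery", "home", "urgent_care")
_COUGH_MEDS = [("benzonatate 100mg capsule", "benzonatate"),
               ("dextromethorphan hbr syrup", "dextromethorphan")]
_EXCLUDED_MEDS = [("dextromethorphan-guaifenesin syrup", "dextromethorphan-guaifenesin"),
                  ("guaifenesin 600mg tablet", "guaifenesin"),
                  ("codeine-promethazine syrup", "codeine-promethazine")]


def _seasonal_day(rng, start: _dt.date, max_offset: int, amplitude: float, phase: int) -> int:
    """Rejection-sample a day offset whose month follows
    rate(m) = 1 + A cos(2 pi (m - phase) / 12)."""
    for _ in range(200):
        off = int(rng.integers(0, max_offset + 1))
        month = (start + _dt.timedelta(days=off)).month
        w = 1.0 + amplitude * math.cos(2.0 * math.pi * (month - phase) / 12.0)
        if rng.random() * (1.0 + abs(amplitude)) < w:
            return off
    return int(rng.integers(0, max_offset + 1))


def gen_population(config: SimConfig, triggers: TriggerLexicon | None = None) -> PopulationBundle:
    """Generate a patient population with planted CC ground truth.

    CC patients receive encounter sets qualifying under
    ``config.cc_params`` by construction; claims-only CC patients
    qualify only once claim encounters are added; all other patients'
    record streams are certified non-qualifying by the brute-force
    oracle. Exclusion statuses (ACE use, age, enrollment gap) are
    planted at the configured fractions and recorded in the manifest.
    """
    triggers = triggers or default_triggers()
    _check_template_bank(triggers)
    rng = np.random.default_rng(config.seed + 1)
    params = config.cc_params
    obs_days = config.observation_months * 30 + 14  # generous cover of 24 calendar months

    n = config.n_patients
    statuses = rng.choice(
        ["ace", "age", "enrollment", "eligible"],
        size=n,
        p=[config.ace_fraction, config.age_ineligible_fraction,
           config.enrollment_gap_fraction,
           1.0 - config.ace_fraction - config.age_ineligible_fraction
           - config.enrollment_gap_fraction],
    )
    eligible_idx = np.flatnonzero(statuses == "eligible")
    n_eligible = len(eligible_idx)
    n_cc = round(config.cc_fraction * n_eligible)
    n_claims_only = round(config.claims_only_cc_fraction * n_eligible)
    if config.cc_fraction > 0 and n_cc == 0:
        raise ValueError("cc_fraction unrealizable: no CC patients at this n_patients")
    if n_cc + n_claims_only > n_eligible:
        raise ValueError("cc_fraction + claims_only_cc_fraction exceed the eligible pool")
    perm = rng.permutation(n_eligible)
    cc_set = set(eligible_idx[perm[:n_cc]])
    claims_only_set = set(eligible_idx[perm[n_cc: n_cc + n_claims_only]])

    bands = list(config.age_band_mixture)
    band_p = np.array([config.age_band_mixture[b] for b in bands], dtype=float)
    band_p /= band_p.sum()
    regions = list(config.region_mixture)
    region_p = np.array([config.region_mixture[r] for r in regions], dtype=float)
    region_p /= region_p.sum()
    id_horizon = (config.identification_end - config.identification_start).days

    attr_names = list(config.attribution_mixture)
    attr_p = np.array([config.attribution_mixture[a] for a in attr_names], dtype=float)
    attr_p /= attr_p.sum()

    patients: list[PatientRecord] = []
    notes: list[ProviderNote] = []
    dx_rows, rx_rows, claim_rows = [], [], []
    manifest_patients = {}
    note_counter = 0

    def add_note(pid: str, date: _dt.date, label: ContextLabel) -> str:
        nonlocal note_counter
        text, planted = _build_note_text(rng, [label])
        nid = f"PN{note_counter:06d}"
        note_counter += 1
        notes.append(ProviderNote(nid, pid, date, text))
        return nid

    def add_encounter_record(pid: str, date: _dt.date, category: EncounterCategory):
        if category == EncounterCategory.NLP_NOTE:
            add_note(pid, date, ContextLabel.POSITIVE)
        elif category == EncounterCategory.DIAGNOSIS:
            setting = _QUALIFYING_SETTINGS[rng.integers(len(_QUALIFYING_SETTINGS))]
            dx_rows.append((pid, date, "ICD-10-CM", "R05", setting))
        elif category == EncounterCategory.MEDICATION_ORDER:
            name, ingr = _COUGH_MEDS[rng.integers(len(_COUGH_MEDS))]
            rx_rows.append((pid, date, name, ingr))
        elif category == EncounterCategory.CLAIM_FILL:
            claim_rows.append((pid, date, "fill", _COUGH_MEDS[rng.integers(2)][1]))
        else:
            claim_rows.append((pid, date, "diagnosis", "R05"))

    def pick_categories(attr: str, k: int) -> list[EncounterCategory]:
        structured = [EncounterCategory.DIAGNOSIS, EncounterCategory.MEDICATION_ORDER]
        if attr == "nlp_only":
            return [EncounterCategory.NLP_NOTE] * k
        if attr == "structured_only":
            return [structured[rng.integers(2)] for _ in range(k)]
        cats = [EncounterCategory.NLP_NOTE, structured[rng.integers(2)]]
        while len(cats) < k:
            cats.append([EncounterCategory.NLP_NOTE, *structured][rng.integers(3)])
        rng.shuffle(cats)
        return cats

    for i in range(n):
        pid = f"P{i:06d}"
        status = str(statuses[i])
        index_offset = int(rng.integers(0, id_horizon + 1))
        index_date = config.identification_start + _dt.timedelta(days=index_offset)
        if status == "enrollment":
            enroll_days = int(rng.integers(120, 600))  # under the 24-month requirement
        else:
            enroll_days = int(rng.integers(obs_days + 45, obs_days + 400))
        span = EnrollmentSpan(index_date, index_date + _dt.timedelta(days=enroll_days))
        if status == "age":
            age = int(rng.integers(8, 18)) if rng.random() < 0.5 else int(rng.integers(86, 96))
        else:
            lo, hi = bands[int(rng.choice(len(bands), p=band_p))]
            age = int(rng.integers(lo, hi + 1))
        sex = "F" if rng.random() < config.female_fraction else "M"
        region = regions[int(rng.choice(len(regions), p=region_p))]
        patients.append(
            PatientRecord(
                patient_id=pid, birth_year=index_date.year - age, sex=sex,
                region=region, enrollment_spans=[span],
                ace_inhibitor_flag=(status == "ace"),
            )
        )
        if status == "ace":
            rx_rows.append((pid, index_date + _dt.timedelta(days=int(rng.integers(0, obs_days))),
                            "lisinopril 10mg tablet", "lisinopril"))

        entry = {
            "status": status, "true_cc": False, "claims_only_cc": False,
            "attribution": None, "encounters": [], "claim_encounters": [],
            "eligibility_date": None, "claims_eligibility_date": None, "gap_days": None,
        }

        is_cc = i in cc_set
        is_claims_only = i in claims_only_set
        if status == "eligible" and (is_cc or is_claims_only):
            g = int(rng.integers(params.span_min_days, params.window_days + 1))
            # seasonality is planted on the eligibility date itself,
            # which is what the monthly histogram bins
            last_off = _seasonal_day(rng, index_date + _dt.timedelta(days=g),
                                     obs_days - g - 70,
                                     config.seasonal_amplitude, config.seasonal_phase_month)
            d_last = index_date + _dt.timedelta(days=g + last_off)
            d1 = d_last - _dt.timedelta(days=g)
            mid_off = int(rng.integers(1, g))
            d_mid = d1 + _dt.timedelta(days=mid_off)
            if is_cc:
                attr = attr_names[int(rng.choice(len(attr_names), p=attr_p))]
                cats = pick_categories(attr, params.k_min)
                days = [d1, d_mid, d_last]
                planted = list(zip(days, cats))
                n_extra = int(rng.poisson(config.extra_cc_encounter_rate))
                extra_pool = sorted({int(x) for x in
                                     rng.integers(1, 60, size=n_extra)}) if n_extra else []
                for off in extra_pool:
                    d = d_last + _dt.timedelta(days=off)
                    if d <= span.end:
                        planted.append((d, pick_categories(attr, 1)[0]))
                qualifies, elig = brute_force_cc([d for d, _ in planted], params)
                assert qualifies and elig == d_last, "planted CC set failed the subset oracle"
                for d, c in planted:
                    add_encounter_record(pid, d, c)
                entry.update(
                    true_cc=True, attribution=attr,
                    encounters=[(d.isoformat(), c.value) for d, c in planted],
                    eligibility_date=d_last.isoformat(),
                    gap_days=(d_last - d1).days,
                )
            else:
                # qualifies only when the claim encounter joins the two EHR ones
                ehr = [(d1, EncounterCategory.DIAGNOSIS if rng.random() < 0.5
                        else EncounterCategory.NLP_NOTE),
                       (d_last, EncounterCategory.MEDICATION_ORDER)]
                claim_cat = (EncounterCategory.CLAIM_FILL if rng.random() < 0.5
                             else EncounterCategory.CLAIM_DIAGNOSIS)
                q_ehr, _ = brute_force_cc([d for d, _ in ehr], params)
                q_all, elig = brute_force_cc([d1, d_mid, d_last], params)
                assert not q_ehr and q_all and elig == d_last
                for d, c in ehr:
                    add_encounter_record(pid, d, c)
                add_encounter_record(pid, d_mid, claim_cat)
                entry.update(
                    claims_only_cc=True,
                    encounters=[(d.isoformat(), c.value) for d, c in ehr],
                    claim_encounters=[(d_mid.isoformat(), claim_cat.value)],
                    claims_eligibility_date=d_last.isoformat(),
                )
        elif status == "eligible":
            # background, certified non-qualifying (with and without claims)
            for _ in range(40):
                k = int(rng.poisson(config.background_encounter_rate))
                k = min(k, 4)
                offs = sorted({int(x) for x in rng.integers(0, obs_days, size=k)})
                days = [index_date + _dt.timedelta(days=o) for o in offs]
                if not brute_force_cc(days, params)[0]:
                    break
            else:
                days = []
            cats = []
            for d in days:
                c = [EncounterCategory.NLP_NOTE, EncounterCategory.DIAGNOSIS,
                     EncounterCategory.MEDICATION_ORDER][rng.integers(3)]
                cats.append(c)
                add_encounter_record(pid, d, c)
            entry["encounters"] = [(d.isoformat(), c.value) for d, c in zip(days, cats)]

        # non-qualifying distractor records: wrong setting, wrong code,
        # excluded medication, or a non-positive note
        if rng.random() < config.distractor_rate:
            d = index_date + _dt.timedelta(days=int(rng.integers(0, obs_days)))
            kind = rng.integers(4)
            if kind == 0:
                dx_rows.append((pid, d, "ICD-10-CM", "R05", "inpatient"))
            elif kind == 1:
                dx_rows.append((pid, d, "ICD-10-CM", "J45.9", "ambulatory"))
            elif kind == 2:
                name, ingr = _EXCLUDED_MEDS[rng.integers(len(_EXCLUDED_MEDS))]
                rx_rows.append((pid, d, name, ingr))
            else:
                lab = [ContextLabel.NEGATED, ContextLabel.HYPOTHETICAL,
                       ContextLabel.NOT_PATIENT, ContextLabel.OTHER][rng.integers(4)]
                add_note(pid, d, lab)

        manifest_patients[pid] = entry

    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "date", "code_system", "code", "setting"])
    orders = pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_name", "ingredient"])
    claims = pd.DataFrame(claim_rows, columns=["patient_id", "date", "kind", "code_or_ingredient"])
    for df in (diagnoses, orders, claims):
        df.sort_values(list(df.columns[:2]), inplace=True, kind="stable")
        df.reset_index(drop=True, inplace=True)

    status_counts = pd.Series(statuses).value_counts().to_dict()
    manifest = {
        "seed": config.seed,
        "n_patients": n,
        "n_eligible": int(n_eligible),
        "n_cc": int(n_cc),
        "n_claims_only_cc": int(n_claims_only),
        "exclusion_counts": {k: int(v) for k, v in status_counts.items() if k != "eligible"},
        "cc_params": {"k_min": params.k_min, "span_min_days": params.span_min_days,
                      "window_days": params.window_days},
        "patients": manifest_patients,
    }
    return PopulationBundle(patients=patients, notes=notes, diagnoses=diagnoses,
                            orders=orders, claims=claims, manifest=manifest)


# ------------------------------------------------------------ utilization

DEFAULT_PPPM_RATES = {
    "office": 1.29, "hospital_outpatient": 1.09, "er": 0.12,
    "inpatient": 0.02, "pharmacy": 3.18, "other_medical": 0.30,
}
DEFAULT_EVENT_COSTS = {
    "office": 171.0, "hospital_outpatient": 505.0, "er": 517.0,
    "inpatient": 23_400.0, "pharmacy": 151.0, "other_medical": 500.0,
}


def gen_utilization(
    patient_index_dates: dict[str, _dt.date],
    months: float = 24.0,
    seed: int = 0,
    pppm_rates: Optional[dict] = None,
    event_costs: Optional[dict] = None,
) -> pd.DataFrame:
    """Utilization records with known per-channel PPPM rates.

    Per patient and channel, event counts are Poisson(rate x months)
    and event costs exponential with the configured mean, so recovered
    PPPM means converge to rate (counts) and rate x mean-cost (costs).
    """
    rng = np.random.default_rng(seed + 7)
    rates = dict(pppm_rates or DEFAULT_PPPM_RATES)
    costs = dict(event_costs or DEFAULT_EVENT_COSTS)
    horizon = int(months * 30)
    rows = []
    for pid, start in sorted(patient_index_dates.items()):
        for channel, rate in rates.items():
            for _ in range(int(rng.poisson(rate * months))):
                date = start + _dt.timedelta(days=int(rng.integers(0, horizon)))
                cost = float(rng.exponential(costs[channel]))
                days = int(1 + rng.poisson(3)) if channel == "inpatient" else 0
                rows.append((pid, date, channel, round(cost, 2), days))
    return pd.DataFrame(rows, columns=["patient_id", "date", "channel", "cost", "inpatient_days"])


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
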