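"""Config-driven orchestration of the full phenotyping pipeline.

Each stage reads and writes the plain-text formats of
:mod:`coughphen.io` inside a working directory and appends a JSON line
to ``run_log.jsonl`` (stage, input hashes, in/out counts, seed). The
``run_all`` chain is fail-fast. Configuration is one YAML mapping;
any key can be overridden by an environment variable
``COUGHPHEN_<KEY>`` (upper-cased).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cc_rule, characterize, encounters, io, metrics, nlp, synth
from .types import ContextLabel, EnrollmentSpan, parse_date


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "workdir": "coughphen_run",
    "mode": "ehr_only",
    "engine": "rules",           # rules | model
    "model_path": None,
    "n_patients": 10_000,
    "n_notes": 1000,
    "cc_params": {"k_min": 3, "span_min_days": 56, "window_days": 120,
                  "collapse_same_day": False},
    "cohort": {"identification_start": "2016-01-01",
               "identification_end": "2017-03-31",
               "age_min": 18, "age_max": 85,
               "min_enrollment_months": 24,
               "exclude_ace_inhibitor": True},
    "sim": {},                   # extra SimConfig overrides
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for k, v in user.items():
            if k not in cfg:
                raise ConfigError(f"{path}: unknown config key {k!r}")
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k in list(cfg):
        env = os.environ.get(f"COUGHPHEN_{k.upper()}")
        if env is not None and not isinstance(cfg[k], dict):
            cfg[k] = yaml.safe_load(env)
    if cfg["mode"] not in {"ehr_only", "ehr_plus_claims"}:
        raise ConfigError("mode must be ehr_only or ehr_plus_claims")
    if cfg["engine"] not in {"rules", "model"}:
        raise ConfigError("engine must be rules or model")
    return cfg


def _cc_params(cfg) -> cc_rule.CCParameters:
    try:
        return cc_rule.CCParameters(**cfg["cc_params"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad cc_params: {exc}") from exc


def _cohort_spec(cfg) -> encounters.CohortSpec:
    c = dict(cfg["cohort"])
    try:
        c["identification_start"] = parse_date(c["identification_start"])
        c["identification_end"] = parse_date(c["identification_end"])
        return encounters.CohortSpec(**c)
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"bad cohort spec: {exc}") from exc


def _log(workdir: Path, stage: str, **info) -> None:
    entry = {"stage": stage, "version": __version__,
             "time": _dt.datetime.now().isoformat(timespec="seconds"), **info}
    with open(workdir / "run_log.jsonl", "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry) + "\n")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


# ----------------------------------------------------------------- stages

def simulate(cfg: dict) -> Path:
    """Generate corpus + population into the working directory."""
    wd = Path(cfg["workdir"])
    wd.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg.get("sim") or {})
    sim = synth.SimConfig(seed=int(cfg["seed"]), n_patients=int(cfg["n_patients"]),
                          n_notes=int(cfg["n_notes"]), cc_params=_cc_params(cfg),
                          **sim_kwargs)
    corpus = synth.gen_corpus(sim)
    pop = synth.gen_population(sim)
    io.write_notes(corpus.notes, wd / "corpus_notes.jsonl")
    io.write_annotations(corpus.gold, wd / "corpus_gold.tsv")
    io.write_annotations(corpus.annotator_spans, wd / "corpus_annotators.tsv")
    synth.write_manifest(corpus.manifest, wd / "corpus_manifest.json")
    io.write_notes(pop.notes, wd / "notes.jsonl")
    io.write_event_table(pop.diagnoses, wd / "diagnoses.csv")
    io.write_event_table(pop.orders, wd / "orders.csv")
    io.write_event_table(pop.claims, wd / "claims.csv")
    io.write_patients(pop.patients, wd / "patients.csv")
    synth.write_manifest(pop.manifest, wd / "population_manifest.json")
    _log(wd, "simulate", seed=cfg["seed"], n_patients=len(pop.patients),
         n_notes=len(pop.notes), n_corpus_notes=len(corpus.notes))
    return wd


def train(cfg: dict) -> Path:
    """Train the context classifier on the simulated corpus splits."""
    wd = Path(cfg["workdir"])
    notes = io.read_notes(wd / "corpus_notes.jsonl")
    gold = [a for a in io.read_annotations(wd / "corpus_gold.tsv", notes)
            if a.annotator_id == "adjudicated"]
    with open(wd / "corpus_manifest.json", encoding="utf-8") as fh:
        splits = json.load(fh)["splits"]
    by_split = {
        name: ([n for n in notes if n.note_id in set(ids)],
               [a for a in gold if a.note_id in set(ids)])
        for name, ids in splits.items()
    }
    model = nlp.train_context_model(
        *by_split["train"], *by_split["val"], seed=int(cfg["seed"]))
    out = Path(cfg["model_path"] or wd / "context_model.joblib")
    nlp.save_model(model, out)
    _log(wd, "train", seed=cfg["seed"],
         n_train_mentions=model.training_meta_["n_train_mentions"],
         corpus_hash=model.training_meta_["corpus_hash"])
    return out


def extract(cfg: dict) -> Path:
    """Extract and classify mentions over the population notes."""
    wd = Path(cfg["workdir"])
    notes = io.read_notes(wd / "notes.jsonl")
    if cfg["engine"] == "model":
        path = cfg["model_path"] or wd / "context_model.joblib"
        engine = nlp.load_model(path)
    else:
        engine = "rules"
    classified = nlp.classify_corpus(notes, engine)
    out = wd / "mentions.tsv"
    io.write_classified_mentions(classified, out)
    _log(wd, "extract", engine=cfg["engine"], n_notes=len(notes),
         n_mentions=len(classified), input_hash=_hash_file(wd / "notes.jsonl"))
    return out


def build_encounters(cfg: dict) -> Path:
    wd = Path(cfg["workdir"])
    mentions = io.read_classified_mentions(wd / "mentions.tsv")
    diagnoses = io.read_event_table(wd / "diagnoses.csv", "diagnosis")
    orders = io.read_event_table(wd / "orders.csv", "medication_order")
    claims_path = wd / "claims.csv"
    claims = io.read_event_table(claims_path, "claim") if claims_path.exists() else None
    encs = encounters.build_encounters(mentions, diagnoses, orders, claims)
    out = wd / "encounters.csv"
    io.write_encounters(encs, out)
    _log(wd, "build-encounters", n_in=len(mentions) + len(diagnoses) + len(orders)
         + (len(claims) if claims is not None else 0), n_encounters=len(encs))
    return out


def phenotype(cfg: dict) -> Path:
    wd = Path(cfg["workdir"])
    params = _cc_params(cfg)
    spec = _cohort_spec(cfg)
    patients = io.read_patients(wd / "patients.csv")
    orders = io.read_event_table(wd / "orders.csv", "medication_order")
    claims_path = wd / "claims.csv"
    claims = io.read_event_table(claims_path, "claim") if claims_path.exists() else None
    selection = encounters.select_cohort(patients, spec, orders=orders, claims=claims)
    encs = io.read_encounters(wd / "encounters.csv")
    enrollment = {p.patient_id: p.enrollment_spans for p in patients}
    results, summary = cc_rule.run_cohort(
        encs, params, mode=cfg["mode"],
        cohort_ids=sorted(selection.eligible), enrollment=enrollment)
    io.write_cc_results(results, wd / "cc_results.csv")
    hist = cc_rule.eligibility_histogram(results)
    hist.rename("n").rename_axis("month").to_csv(wd / "eligibility_histogram.csv")
    summary["exclusion_ledger"] = dict(selection.exclusion_ledger)
    summary["gap_statistics"] = cc_rule.gap_statistics(results)
    with open(wd / "phenotype_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    _log(wd, "phenotype", mode=cfg["mode"], cohort_size=summary["cohort_size"],
         n_cc=summary["n_cc"])
    return wd / "cc_results.csv"


def evaluate(cfg: dict) -> Path:
    """Evaluate the configured engine on the held-out corpus test split."""
    wd = Path(cfg["workdir"])
    notes = io.read_notes(wd / "corpus_notes.jsonl")
    gold = io.read_annotations(wd / "corpus_gold.tsv", notes)
    with open(wd / "corpus_manifest.json", encoding="utf-8") as fh:
        test_ids = set(json.load(fh)["splits"]["test"])
    test_notes = [n for n in notes if n.note_id in test_ids]
    test_gold = [a for a in gold if a.note_id in test_ids]
    if not test_gold:
        raise io.DataValidationError("empty test split")
    if cfg["engine"] == "model":
        engine = nlp.load_model(cfg["model_path"] or wd / "context_model.joblib")
    else:
        engine = "rules"
    predictions = [m for _, m in nlp.classify_corpus(test_notes, engine)]
    report = metrics.evaluate_model(test_gold, predictions)
    report.to_tsv(wd / "model_metrics.tsv")
    with open(wd / "model_metrics.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    _log(wd, "evaluate", engine=cfg["engine"], n_test_notes=len(test_notes),
         n_gold=len(test_gold))
    return wd / "model_metrics.tsv"


def annotate_agreement(cfg: dict) -> float:
    wd = Path(cfg["workdir"])
    notes = io.read_notes(wd / "corpus_notes.jsonl")
    spans = io.read_annotations(wd / "corpus_annotators.tsv", notes)
    alpha = metrics.krippendorff_alpha(spans)
    with open(wd / "agreement.json", "w", encoding="utf-8") as fh:
        json.dump({"krippendorff_alpha": alpha,
                   "n_annotations": len(spans)}, fh, indent=1)
    _log(wd, "annotate-agreement", alpha=alpha)
    return alpha


def characterize_stage(cfg: dict, grouper_path=None) -> Path:
    wd = Path(cfg["workdir"])
    patients = io.read_patients(wd / "patients.csv")
    results_df = pd.read_csv(wd / "cc_results.csv", dtype={"patient_id": str})
    cc_ids = set(results_df.loc[results_df["is_cc"] == 1, "patient_id"])

    class _R:  # lightweight stand-in with the fields characterize uses
        def __init__(self, pid):
            self.patient_id, self.is_cc = pid, True

    cc_results = [_R(pid) for pid in sorted(cc_ids)]
    for p in patients:
        if p.enrollment_spans:
            p.index_date = p.enrollment_spans[0].start
    demo = characterize.summarize_demographics(patients, cc_results)
    demo.to_csv(wd / "demographics.tsv", sep="\t", index=False)
    if grouper_path:
        grouper = characterize.CodeGrouper.from_csv(grouper_path)
        dx = io.read_event_table(wd / "diagnoses.csv", "diagnosis")
        comorb = characterize.comorbidity_prevalence(dx, grouper, cc_results)
        comorb.to_csv(wd / "comorbidities.tsv", sep="\t", index=False)
    util_path = wd / "utilization.csv"
    if util_path.exists():
        util = pd.read_csv(util_path, dtype={"patient_id": str})
        util["date"] = util["date"].map(parse_date)
        pppm = characterize.pppm_summary(util, cc_results)
        pppm.to_csv(wd / "pppm.tsv", sep="\t", index=False)
    _log(wd, "characterize", n_cc=len(cc_ids))
    return wd / "demographics.tsv"


def run_all(cfg: dict) -> dict:
    """Simulate -> agreement -> train -> extract -> encounters ->
    phenotype -> evaluate -> characterize, fail-fast."""
    simulate(cfg)
    annotate_agreement(cfg)
    if cfg["engine"] == "model":
        train(cfg)
    extract(cfg)
    build_encounters(cfg)
    phenotype(cfg)
    evaluate(cfg)
    characterize_stage(cfg)
    wd = Path(cfg["workdir"])
    with open(wd / "phenotype_summary.json", encoding="utf-8") as fh:
        return json.load(fh)
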