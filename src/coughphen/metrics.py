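"""Diagnostic-accuracy metrics and annotation-agreement statistics.

Entity-level evaluation matches predicted mention spans against gold
spans (exact-offset by default); context classification is then scored
over the matched mentions, one-vs-rest per label, so that the positive
and negated classes each get their own precision / recall / F1 row with
their own support — the shape of a standard NLP model report.

Krippendorff's alpha (nominal) quantifies chance-corrected
inter-annotator agreement: alpha = 1 - Do/De, observed over expected
disagreement, computed from the coincidence matrix of pairable values.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AnnotationSpan, ClassifiedMention, ConfusionCounts, ContextLabel

logger = logging.getLogger(__name__)

#: Marker for a metric whose denominator is zero.
UNDEFINED = None


def precision(counts: ConfusionCounts) -> Optional[float]:
    """PPV = TP/(TP+FP); None when undefined (no predictions)."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else UNDEFINED


def recall(counts: ConfusionCounts) -> Optional[float]:
    """Sensitivity = TP/(TP+FN); None when undefined (no gold)."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else UNDEFINED


def f1(p: Optional[float], r: Optional[float]) -> Optional[float]:
    """Harmonic mean 2pr/(p+r); symmetric in p and r."""
    if p is UNDEFINED or r is UNDEFINED:
        return UNDEFINED
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


# ------------------------------------------------------------ span match

def match_spans(
    gold: Sequence, predicted: Sequence, policy: str = "exact"
) -> tuple[ConfusionCounts, list[tuple]]:
    """Match predicted spans to gold spans; each span matches at most once.

    Spans are any objects with ``note_id``, ``start``, ``end``.
    ``policy='exact'`` requires identical offsets; ``policy='overlap'``
    accepts any character overlap, matched greedily by left offset
    (ambiguous multi-overlaps are logged). Returns the entity-level
    confusion counts (TN undefined) and the matched (gold, predicted)
    pairs.
    """
    if policy not in {"exact", "overlap"}:
        raise ValueError("policy must be 'exact' or 'overlap'")
    pairs: list[tuple] = []
    if policy == "exact":
        index = {(g.note_id, g.start, g.end): g for g in gold}
        if len(index) != len(gold):
            raise ValueError("duplicate gold spans")
        used = set()
        for p in predicted:
            key = (p.note_id, p.start, p.end)
            if key in index and key not in used:
                used.add(key)
                pairs.append((index[key], p))
    else:
        by_note: dict[str, list] = defaultdict(list)
        for g in gold:
            by_note[g.note_id].append(g)
        for lst in by_note.values():
            lst.sort(key=lambda g: (g.start, g.end))
        matched_gold = set()
        for p in sorted(predicted, key=lambda p: (p.note_id, p.start, p.end)):
            cands = [
                g for g in by_note.get(p.note_id, [])
                if id(g) not in matched_gold and g.start < p.end and g.end > p.start
            ]
            if len(cands) > 1:
                logger.info("ambiguous overlap for span %s:%d-%d; greedy by left offset",
                            p.note_id, p.start, p.end)
            if cands:
                g = cands[0]
                matched_gold.add(id(g))
                pairs.append((g, p))
    tp = len(pairs)
    counts = ConfusionCounts(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)
    return counts, pairs


def one_vs_rest_counts(
    gold_labels: Sequence[ContextLabel],
    predicted_labels: Sequence[ContextLabel],
    positive_class: ContextLabel,
) -> ConfusionCounts:
    """Binary confusion counts treating one label as the positive class."""
    if len(gold_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    tp = fp = fn = tn = 0
    for g, p in zip(gold_labels, predicted_labels):
        gp, pp = g == positive_class, p == positive_class
        if gp and pp:
            tp += 1
        elif pp:
            fp += 1
        elif gp:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# -------------------------------------------------------------- alpha

def krippendorff_alpha(
    annotations: Iterable[AnnotationSpan] | Mapping[str, Sequence],
) -> Optional[float]:
    """Krippendorff's alpha for nominal data, any number of annotators,
    missing values allowed.

    Accepts either annotation spans (units are (note_id, start, end))
    or a mapping unit -> sequence of labels. alpha = 1 - Do/De where Do
    and De come from the coincidence matrix over units with >= 2
    ratings; 1.0 is perfect agreement, 0 is chance. None when fewer
    than two multiply-rated units or a single observed label with no
    possible disagreement denominator.
    """
    units: dict = defaultdict(list)
    if isinstance(annotations, Mapping):
        for u, labels in annotations.items():
            units[u] = [str(v) for v in labels]
    else:
        for a in annotations:
            units[(a.note_id, a.start, a.end)].append(str(a.label.value))
    pairable = {u: vals for u, vals in units.items() if len(vals) >= 2}
    if len(pairable) < 2:
        return UNDEFINED
    coincidence: Counter = Counter()
    totals: Counter = Counter()
    for vals in pairable.values():
        m = len(vals)
        for i, c in enumerate(vals):
            totals[c] += 1
            for j, k in enumerate(vals):
                if i != j:
                    coincidence[(c, k)] += 1.0 / (m - 1)
    n = sum(totals.values())
    observed_disagreement = sum(v for (c, k), v in coincidence.items() if c != k)
    expected_pairs = sum(
        totals[c] * totals[k] for c in totals for k in totals if c != k
    )
    if expected_pairs == 0:
        # every rating identical: perfect agreement by convention
        return 1.0 if observed_disagreement == 0 else UNDEFINED
    return 1.0 - (n - 1) * observed_disagreement / expected_pairs


# ------------------------------------------------------------- reporting

@dataclass
class MetricsReport:
    """Per-concept metric rows mirroring a model-performance table."""

    rows: pd.DataFrame  # concept, model_type, precision, recall, f1, support
    conditioning: str = "matched_mentions"

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        for col in ("precision", "recall", "f1"):
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.2f}")
        out.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "conditioning": self.conditioning,
            "rows": self.rows.to_dict(orient="records"),
        }


def evaluate_model(
    gold: Sequence[AnnotationSpan],
    predictions: Sequence[ClassifiedMention],
    policy: str = "exact",
) -> MetricsReport:
    """Score predictions against a gold test split.

    Three rows: entity recognition over all spans; POSITIVE and NEGATED
    classification one-vs-rest over the entity-matched mentions (support
    = gold occurrences of the class among matched mentions).
    """
    if not gold:
        raise ValueError("empty gold test split")
    entity_counts, pairs = match_spans(gold, predictions, policy=policy)
    gold_labels = [g.label for g, _ in pairs]
    pred_labels = [ContextLabel(p.label) for _, p in pairs]

    rows = []
    p_ent, r_ent = precision(entity_counts), recall(entity_counts)
    rows.append({
        "concept": "Cough mention", "model_type": "Entity recognition",
        "precision": p_ent, "recall": r_ent, "f1": f1(p_ent, r_ent),
        "support": len(gold),
    })
    for concept, cls in (
        ("Positive cough mention", ContextLabel.POSITIVE),
        ("Negative cough mention", ContextLabel.NEGATED),
    ):
        counts = one_vs_rest_counts(gold_labels, pred_labels, cls)
        p, r = precision(counts), recall(counts)
        rows.append({
            "concept": concept, "model_type": "Classification",
            "precision": p, "recall": r, "f1": f1(p, r),
            "support": counts.tp + counts.fn,
        })
    return MetricsReport(rows=pd.DataFrame(rows))
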