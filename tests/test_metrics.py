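"""Diagnostic-accuracy metrics and Krippendorff's alpha."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coughphen import ContextLabel, classify_corpus, evaluate_model, f1, precision, recall
from coughphen.metrics import krippendorff_alpha, match_spans, one_vs_rest_counts
from coughphen.types import AnnotationSpan, ClassifiedMention, ConfusionCounts


@pytest.mark.parametrize(
    "p, r, expected",
    [
        (0.96, 0.68, 0.80),  # positive-context row of the model report
        (1.0, 1.0, 1.0),
        (0.5, 0.5, 0.5),
        (1.0, 0.0, 0.0),
    ],
)
def test_f1_worked_examples(p, r, expected):
    assert round(f1(p, r), 2) == expected
    assert f1(p, r) == f1(r, p)  # symmetric


def test_f1_of_rounded_inputs_matches_printed_value_to_last_digit():
    # recomputing from 2-dp precision/recall can differ from an F1
    # computed before rounding by up to one unit in the last digit
    assert abs(f1(0.96, 0.84) - 0.89) <= 0.01


@given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_f1_between_min_and_mean(p, r):
    v = f1(p, r)
    assert min(p, r) - 1e-12 <= v <= (p + r) / 2 + 1e-12


def test_undefined_metrics_are_markers_not_zero():
    assert precision(ConfusionCounts(0, 0, 5)) is None
    assert recall(ConfusionCounts(0, 5, 0)) is None
    assert f1(None, 0.5) is None


def gold_span(i, note="n1", label=ContextLabel.POSITIVE):
    return AnnotationSpan(note, 10 * i, 10 * i + 5, label, "adjudicated")


def pred_span(i, note="n1", label=ContextLabel.POSITIVE):
    return ClassifiedMention(note, 10 * i, 10 * i + 5, "cough", "cough", label, 1.0, "rules")


def test_match_spans_identity_and_disjoint():
    gold = [gold_span(i) for i in range(4)]
    counts, pairs = match_spans(gold, [pred_span(i) for i in range(4)])
    assert (counts.tp, counts.fp, counts.fn) == (4, 0, 0)
    counts, _ = match_spans(gold, [pred_span(i + 10) for i in range(3)])
    assert (counts.tp, counts.fp, counts.fn) == (0, 3, 4)


def test_match_spans_conservation_under_corruption():
    """Dropping d gold spans and shifting s others gives FN=d+s, FP=s."""
    rng = np.random.default_rng(5)
    gold = [gold_span(i) for i in range(30)]
    d, s = 6, 4
    idx = rng.permutation(30)
    dropped, shifted = set(idx[:d]), set(idx[d: d + s])
    preds = []
    for i in range(30):
        if i in dropped:
            continue
        if i in shifted:
            preds.append(pred_span(100 + i))
        else:
            preds.append(pred_span(i))
    counts, _ = match_spans(gold, preds)
    assert (counts.fn, counts.fp) == (d + s, s)
    assert counts.tp + counts.fn == len(gold)
    assert counts.tp + counts.fp == len(preds)


def test_overlap_policy_matches_shifted_spans():
    gold = [AnnotationSpan("n1", 0, 5, ContextLabel.POSITIVE, "a")]
    pred = [ClassifiedMention("n1", 2, 7, "cough", "cough", ContextLabel.POSITIVE, 1.0, "rules")]
    exact, _ = match_spans(gold, pred, policy="exact")
    overlap, _ = match_spans(gold, pred, policy="overlap")
    assert exact.tp == 0 and overlap.tp == 1


def test_alpha_perfect_and_frozen_coincidence_example():
    assert krippendorff_alpha({i: ["A", "A"] for i in range(10)}) == 1.0
    # hand-computed coincidence matrix for {(A,A),(A,A),(B,B),(A,B)}:
    # o_AB + o_BA = 2, n_A = 5, n_B = 3, n = 8
    # alpha = 1 - (n-1) * 2 / (2 * 5 * 3) = 1 - 14/30 = 8/15
    units = {1: ["A", "A"], 2: ["A", "A"], 3: ["B", "B"], 4: ["A", "B"]}
    assert krippendorff_alpha(units) == pytest.approx(8 / 15)


def test_alpha_invariant_under_label_renaming():
    units = {1: ["A", "A"], 2: ["A", "B"], 3: ["B", "B"], 4: ["C", "A"]}
    renamed = {u: [{"A": "X", "B": "Y", "C": "Z"}[v] for v in vals]
               for u, vals in units.items()}
    assert krippendorff_alpha(units) == pytest.approx(krippendorff_alpha(renamed))


def test_alpha_near_zero_for_random_labels():
    rng = np.random.default_rng(3)
    units = {i: list(rng.choice(["A", "B", "C"], size=2)) for i in range(1000)}
    assert abs(krippendorff_alpha(units)) < 0.05


def test_alpha_undefined_cases():
    assert krippendorff_alpha({1: ["A", "B"]}) is None          # one pairable unit
    assert krippendorff_alpha({1: ["A"], 2: ["B"]}) is None     # no pairs at all


def test_alpha_from_annotation_spans(corpus):
    spans = [a for a in corpus.annotator_spans]
    assert krippendorff_alpha(spans) == 1.0  # zero disagreement planted


def test_evaluate_model_perfect_predictions(corpus):
    test_ids = set(corpus.splits["test"])
    notes = [n for n in corpus.notes if n.note_id in test_ids]
    gold = [a for a in corpus.gold if a.note_id in test_ids]
    preds = [m for _, m in classify_corpus(notes, "rules")]
    report = evaluate_model(gold, preds)
    rows = report.rows.set_index("concept")
    assert rows["support"]["Cough mention"] == len(gold)
    assert rows["support"]["Positive cough mention"] == sum(
        a.label == ContextLabel.POSITIVE for a in gold
    )
    for concept in rows.index:
        assert rows["precision"][concept] == 1.0
        assert rows["recall"][concept] == 1.0
    # internal consistency: the f1 column equals f1(precision, recall)
    for _, row in report.rows.iterrows():
        assert row["f1"] == pytest.approx(f1(row["precision"], row["recall"]))


def test_positive_label_corruption_shows_as_recall_loss(corpus):
    """Flipping a fraction q of gold-POSITIVE predictions to NEGATED
    drops positive recall to about 1-q."""
    rng = np.random.default_rng(9)
    q = 0.2
    gold = corpus.gold
    notes = corpus.notes
    preds = []
    for _, m in classify_corpus(notes, "rules"):
        label = m.label
        if label == ContextLabel.POSITIVE and rng.random() < q:
            label = ContextLabel.NEGATED
        preds.append(ClassifiedMention(m.note_id, m.start, m.end, m.surface,
                                       m.term, label, 1.0, "rules"))
    report = evaluate_model(gold, preds)
    rec = report.rows.set_index("concept")["recall"]["Positive cough mention"]
    n_pos = sum(a.label == ContextLabel.POSITIVE for a in gold)
    tol = 3 * np.sqrt(q * (1 - q) / n_pos)
    assert abs(rec - (1 - q)) < tol


def test_evaluate_model_empty_gold_raises():
    with pytest.raises(ValueError, match="empty"):
        evaluate_model([], [])


def test_one_vs_rest_counts_conserve():
    g = [ContextLabel.POSITIVE, ContextLabel.NEGATED, ContextLabel.POSITIVE]
    p = [ContextLabel.POSITIVE, ContextLabel.POSITIVE, ContextLabel.NEGATED]
    c = one_vs_rest_counts(g, p, ContextLabel.POSITIVE)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 0)
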