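"""Cough-mention extraction and context classification.

Two stages mirror how cough is identified in provider notes:

1. **Entity recognition** — every word-bounded, case-insensitive match of
   a small closed lexicon (cough, coughed, coughing, coughs, cougher,
   tussis) is a mention candidate. Because the lexicon is closed, entity
   recognition is deterministic and exact.
2. **Context classification** — each mention gets one
   :class:`~coughphen.types.ContextLabel`. Two interchangeable engines
   are provided: a trigger/scope rules engine in the ConText style, and
   :class:`ContextClassifier`, a trainable scikit-learn estimator over
   window features. A mention is POSITIVE iff no qualifying context
   (negation, hypothetical, not-the-patient, other) claims it.

Temporality is deliberately not modelled: "history of cough x 5 weeks"
is classified as a current, positive mention.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .types import ClassifiedMention, ContextLabel, MentionCandidate, ProviderNote

#: The closed cough lexicon. Expectorate terms are deliberately absent:
#: they rarely occur without a cough term alongside.
DEFAULT_LEXICON = ("cough", "coughed", "coughing", "coughs", "cougher", "tussis")

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+|\n+")


def _lexicon_pattern(lexicon: Sequence[str]) -> re.Pattern:
    alts = sorted((re.escape(t) for t in lexicon), key=len, reverse=True)
    return re.compile(r"\b(?:" + "|".join(alts) + r")\b", re.IGNORECASE)


def extract_mentions(
    note: ProviderNote, lexicon: Sequence[str] = DEFAULT_LEXICON
) -> list[MentionCandidate]:
    """All word-bounded, case-insensitive lexicon matches, in document order.

    Empty text yields an empty list. Matches inside longer words
    ("Coughlin") are excluded by the word boundary.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    pattern = _lexicon_pattern(lexicon)
    out = []
    for m in pattern.finditer(note.text):
        out.append(
            MentionCandidate(
                note_id=note.note_id,
                start=m.start(),
                end=m.end(),
                surface=m.group(0),
                term=m.group(0).lower(),
            )
        )
    return out


# ------------------------------------------------------------------ text

def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences. Periods/?/! followed by
    whitespace and newlines are boundaries; clinical notes' fragmentary
    lines count as sentences."""
    spans = []
    pos = 0
    for m in _SENT_SPLIT_RE.finditer(text):
        if m.start() > pos:
            spans.append((pos, m.start()))
        pos = m.end()
    if pos < len(text):
        spans.append((pos, len(text)))
    return spans


def tokenize(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Lowercased tokens with absolute character spans."""
    return [(m.group(0).lower(), offset + m.start(), offset + m.end()) for m in _TOKEN_RE.finditer(text)]


# --------------------------------------------------------------- triggers

#: Precedence when two triggers sit at equal distance from a mention.
_PRECEDENCE = [
    ContextLabel.NEGATED,
    ContextLabel.HYPOTHETICAL,
    ContextLabel.NOT_PATIENT,
    ContextLabel.OTHER,
]


@dataclass
class TriggerLexicon:
    """Directional context triggers with a token scope window.

    ``pre`` triggers scope forward over the following tokens; ``post``
    triggers scope backward. Scope is cut by a sentence boundary or a
    terminator token.
    """

    negation_pre: list[str]
    negation_post: list[str]
    hypothetical_pre: list[str]
    hypothetical_post: list[str]
    not_patient_pre: list[str]
    not_patient_post: list[str]
    other_pre: list[str] = field(default_factory=list)
    other_post: list[str] = field(default_factory=list)
    terminators: list[str] = field(default_factory=list)
    scope_window: int = 6

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        cats = {
            "negation": set(self.negation_pre) | set(self.negation_post),
            "hypothetical": set(self.hypothetical_pre) | set(self.hypothetical_post),
            "not_patient": set(self.not_patient_pre) | set(self.not_patient_post),
            "other": set(self.other_pre) | set(self.other_post),
        }
        names = list(cats)
        for i, a in enumerate(names):
            if not cats[a] and a in ("negation", "hypothetical", "not_patient"):
                raise ValueError(f"trigger list for {a} must be non-empty")
            for b in names[i + 1:]:
                overlap = cats[a] & cats[b]
                if overlap:
                    raise ValueError(f"trigger lists {a}/{b} overlap: {sorted(overlap)}")

    def entries(self):
        """(label, direction, trigger token tuple) for every trigger."""
        groups = [
            (ContextLabel.NEGATED, self.negation_pre, self.negation_post),
            (ContextLabel.HYPOTHETICAL, self.hypothetical_pre, self.hypothetical_post),
            (ContextLabel.NOT_PATIENT, self.not_patient_pre, self.not_patient_post),
            (ContextLabel.OTHER, self.other_pre, self.other_post),
        ]
        for label, pre, post in groups:
            for t in pre:
                yield label, "pre", tuple(tok for tok, _, _ in tokenize(t))
            for t in post:
                yield label, "post", tuple(tok for tok, _, _ in tokenize(t))

    @classmethod
    def from_yaml(cls, path=None) -> "TriggerLexicon":
        if path is None:
            raw = resources.files("coughphen.data").joinpath("triggers.yaml").read_text()
        else:
            with open(path, encoding="utf-8") as fh:
                raw = fh.read()
        cfg = yaml.safe_load(raw)
        return cls(
            negation_pre=cfg["negation"].get("pre", []),
            negation_post=cfg["negation"].get("post", []),
            hypothetical_pre=cfg["hypothetical"].get("pre", []),
            hypothetical_post=cfg["hypothetical"].get("post", []),
            not_patient_pre=cfg["not_patient"].get("pre", []),
            not_patient_post=cfg["not_patient"].get("post", []),
            other_pre=cfg.get("other", {}).get("pre", []),
            other_post=cfg.get("other", {}).get("post", []),
            terminators=cfg.get("terminators", []),
            scope_window=int(cfg.get("scope_window", 6)),
        )


def default_triggers() -> TriggerLexicon:
    return TriggerLexicon.from_yaml(None)


def _find_trigger_hits(tokens, entries):
    """Token-index occurrences of every trigger in a token list.

    Returns (label, direction, first_idx, last_idx) tuples.
    """
    words = [t[0] for t in tokens]
    hits = []
    for label, direction, trig in entries:
        L = len(trig)
        if L == 0:
            continue
        for i in range(len(words) - L + 1):
            if tuple(words[i: i + L]) == trig:
                hits.append((label, direction, i, i + L - 1))
    return hits


def _mention_token_index(tokens, start: int, end: int) -> Optional[int]:
    for idx, (_, s, e) in enumerate(tokens):
        if s < end and e > start:
            return idx
    return None


def classify_context_rules(
    note: ProviderNote,
    mention: MentionCandidate,
    triggers: TriggerLexicon | None = None,
) -> ClassifiedMention:
    """Assign a context label by nearest in-scope trigger.

    Scope runs ``scope_window`` tokens from the trigger in its direction
    and stops at a terminator token; the sentence boundary bounds it
    implicitly (triggers are only sought in the mention's sentence).
    No trigger in scope means POSITIVE. Distance ties are broken by
    precedence NEGATED > HYPOTHETICAL > NOT_PATIENT > OTHER.
    """
    triggers = triggers or default_triggers()
    sent = next(
        (sp for sp in sentence_spans(note.text) if sp[0] <= mention.start < sp[1]),
        (0, len(note.text)),
    )
    tokens = tokenize(note.text[sent[0]: sent[1]], offset=sent[0])
    m_idx = _mention_token_index(tokens, mention.start, mention.end)
    label = ContextLabel.POSITIVE
    if m_idx is not None:
        term_set = {t.lower() for t in triggers.terminators}
        best: Optional[tuple[int, int]] = None  # (distance, precedence rank)
        for lab, direction, first, last in _find_trigger_hits(tokens, triggers.entries()):
            if direction == "pre":
                if not (last < m_idx <= last + triggers.scope_window):
                    continue
                between = range(last + 1, m_idx)
                dist = m_idx - last
            else:
                if not (first > m_idx >= first - triggers.scope_window):
                    continue
                between = range(m_idx + 1, first)
                dist = first - m_idx
            if any(tokens[j][0] in term_set for j in between):
                continue  # scope terminated before reaching the mention
            key = (dist, _PRECEDENCE.index(lab))
            if best is None or key < best:
                best, label = key, lab
    return ClassifiedMention(
        note_id=mention.note_id,
        start=mention.start,
        end=mention.end,
        surface=mention.surface,
        term=mention.term,
        label=label,
        score=1.0,
        method="rules",
    )


# ------------------------------------------------------------- classifier

def mention_features(
    text: str, start: int, end: int, triggers: TriggerLexicon, window: int = 6
) -> dict:
    """Window features for one mention: neighbouring tokens (positional
    and bag), trigger presence/distance per category, sentence position."""
    sent = next((sp for sp in sentence_spans(text) if sp[0] <= start < sp[1]), (0, len(text)))
    tokens = tokenize(text[sent[0]: sent[1]], offset=sent[0])
    m_idx = _mention_token_index(tokens, start, end)
    feats: dict[str, float] = {"bias": 1.0}
    if m_idx is None:
        return feats
    n = len(tokens)
    feats["sent_rel_pos"] = m_idx / max(n - 1, 1)
    feats["sent_len_bucket"] = min(n // 5, 4)
    for off in range(-window, window + 1):
        j = m_idx + off
        if off == 0 or not (0 <= j < n):
            continue
        tok = tokens[j][0]
        feats[f"tok[{off}]={tok}"] = 1.0
        side = "L" if off < 0 else "R"
        feats[f"bag{side}={tok}"] = 1.0
    for lab, direction, first, last in _find_trigger_hits(tokens, triggers.entries()):
        if direction == "pre" and last < m_idx:
            dist = m_idx - last
        elif direction == "post" and first > m_idx:
            dist = first - m_idx
        else:
            continue
        if dist <= window:
            key = f"trig:{lab.value}:{direction}"
            feats[key] = 1.0
            feats[key + ":dist"] = min(feats.get(key + ":dist", window), dist)
    return feats


class ContextClassifier(BaseEstimator, ClassifierMixin):
    """Per-mention context classifier over window features.

    A multinomial logistic regression on sparse window features; the
    POSITIVE decision threshold can be tuned on a validation split to
    maximize recall subject to a minimum precision (precision-first
    operating point). Samples are ``(text, start, end)`` triples and
    labels are :class:`ContextLabel` values (or their string names).

    Parameters
    ----------
    window : int
        Token radius for context features.
    C : float
        Inverse regularization strength of the logistic model.
    ppv_target : float
        Minimum positive-class precision the tuned threshold must meet.
    random_state : int
        Seed for the underlying solver; fixes training exactly.
    """

    def __init__(self, window: int = 6, C: float = 2.0, ppv_target: float = 0.90,
                 random_state: int = 0, triggers: Optional[TriggerLexicon] = None):
        self.window = window
        self.C = C
        self.ppv_target = ppv_target
        self.random_state = random_state
        self.triggers = triggers

    def _featurize(self, X) -> list[dict]:
        trig = self.triggers or default_triggers()
        return [mention_features(text, int(s), int(e), trig, self.window) for text, s, e in X]

    def fit(self, X, y):
        y = np.asarray([ContextLabel(v).value for v in y])
        labels = np.unique(y)
        if len(labels) < 2:
            raise ValueError(
                "corpus has a single context label; a classifier cannot be "
                "trained — use the rule-based engine instead"
            )
        self.vectorizer_ = DictVectorizer(sparse=True)
        M = self.vectorizer_.fit_transform(self._featurize(X))
        self.model_ = LogisticRegression(
            C=self.C, max_iter=2000, random_state=self.random_state
        )
        self.model_.fit(M, y)
        self.classes_ = self.model_.classes_
        self.positive_threshold_ = None
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.vectorizer_.transform(self._featurize(X)))

    def predict(self, X):
        """Argmax labels, with the POSITIVE class additionally gated by
        ``positive_threshold_`` when one has been tuned: an
        argmax-POSITIVE prediction whose positive probability falls
        below the threshold is demoted to the best non-positive class.
        The gate only ever removes positive calls (precision-first); it
        never adds them."""
        proba = self.predict_proba(X)
        classes = self.classes_
        labels = classes[np.argmax(proba, axis=1)]
        thr = getattr(self, "positive_threshold_", None)
        if thr is not None and ContextLabel.POSITIVE.value in classes:
            pos_idx = int(np.where(classes == ContextLabel.POSITIVE.value)[0][0])
            non_pos = [i for i, c in enumerate(classes) if i != pos_idx]
            demote = (labels == ContextLabel.POSITIVE.value) & (proba[:, pos_idx] < thr)
            if demote.any():
                sub = proba[np.ix_(demote, non_pos)]
                labels = labels.copy()
                labels[demote] = classes[np.asarray(non_pos)][np.argmax(sub, axis=1)]
        return labels

    def tune_threshold(self, X_val, y_val) -> Optional[float]:
        """Tune the POSITIVE gate on a validation split: the smallest
        threshold (maximum recall) whose gated precision exceeds
        ``ppv_target``; when even full gating cannot reach the target,
        the most conservative candidate is kept."""
        check_is_fitted(self, "model_")
        y_val = np.asarray([ContextLabel(v).value for v in y_val])
        if ContextLabel.POSITIVE.value not in self.classes_:
            self.positive_threshold_ = None
            return None
        pos_idx = int(np.where(self.classes_ == ContextLabel.POSITIVE.value)[0][0])
        proba = self.predict_proba(X_val)
        argmax_pos = self.classes_[np.argmax(proba, axis=1)] == ContextLabel.POSITIVE.value
        p_pos = proba[:, pos_idx]
        is_pos = y_val == ContextLabel.POSITIVE.value
        candidates = [0.0] + sorted(set(p_pos[argmax_pos]))
        best = None
        fallback = None
        for thr in candidates:
            pred = argmax_pos & (p_pos >= thr)
            tp = int((pred & is_pos).sum())
            fp = int((pred & ~is_pos).sum())
            if tp + fp == 0:
                continue
            ppv = tp / (tp + fp)
            rec = tp / max(int(is_pos.sum()), 1)
            if fallback is None or ppv > fallback[0]:
                fallback = (ppv, thr)
            if ppv > self.ppv_target and (best is None or rec > best[0]):
                best = (rec, thr)
        if best is not None:
            self.positive_threshold_ = best[1]
        else:
            self.positive_threshold_ = fallback[1] if fallback else None
        return self.positive_threshold_


def _corpus_hash(X, y) -> str:
    h = hashlib.sha256()
    for (text, s, e), lab in zip(X, y):
        h.update(repr((text, int(s), int(e), str(lab))).encode())
    return h.hexdigest()[:16]


def mention_training_data(notes, annotations):
    """Turn gold annotations into (text, start, end) samples + labels."""
    by_id = {n.note_id: n for n in notes}
    X, y = [], []
    for a in annotations:
        note = by_id.get(a.note_id)
        if note is None:
            continue
        X.append((note.text, a.start, a.end))
        y.append(a.label.value)
    return X, y


def train_context_model(
    train_notes, train_annotations, val_notes=None, val_annotations=None,
    seed: int = 0, window: int = 6, ppv_target: float = 0.90,
    triggers: TriggerLexicon | None = None,
) -> ContextClassifier:
    """Fit a :class:`ContextClassifier` on an annotated corpus.

    When a validation split is given, the POSITIVE threshold is tuned
    there (precision-first operating point). Raises on a single-label
    corpus, directing the caller to the rules engine.
    """
    X, y = mention_training_data(train_notes, train_annotations)
    clf = ContextClassifier(window=window, ppv_target=ppv_target,
                            random_state=seed, triggers=triggers)
    clf.fit(X, y)
    clf.training_meta_ = {
        "seed": seed,
        "window": window,
        "n_train_mentions": len(X),
        "corpus_hash": _corpus_hash(X, y),
    }
    if val_notes is not None and val_annotations is not None:
        Xv, yv = mention_training_data(val_notes, val_annotations)
        if Xv:
            clf.tune_threshold(Xv, yv)
            clf.training_meta_["positive_threshold"] = clf.positive_threshold_
    return clf


def save_model(model: ContextClassifier, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> ContextClassifier:
    return joblib.load(path)


# ------------------------------------------------------------ batch apply

def classify_corpus(
    notes: Iterable[ProviderNote],
    engine: ContextClassifier | TriggerLexicon | str | None = "rules",
    lexicon: Sequence[str] = DEFAULT_LEXICON,
) -> list[tuple[ProviderNote, ClassifiedMention]]:
    """Extract and classify every mention in a corpus.

    ``engine`` is ``"rules"`` (or a :class:`TriggerLexicon`) for the
    rules engine, or a fitted :class:`ContextClassifier`. Output length
    equals the total mention count.
    """
    notes = list(notes)
    out: list[tuple[ProviderNote, ClassifiedMention]] = []
    if isinstance(engine, ContextClassifier):
        pairs = []
        for note in notes:
            for m in extract_mentions(note, lexicon):
                pairs.append((note, m))
        if pairs:
            X = [(note.text, m.start, m.end) for note, m in pairs]
            proba = engine.predict_proba(X)
            labels = engine.predict(X)
            for (note, m), lab, row in zip(pairs, labels, proba):
                out.append(
                    (note, ClassifiedMention(
                        note_id=m.note_id, start=m.start, end=m.end,
                        surface=m.surface, term=m.term,
                        label=ContextLabel(lab), score=float(row.max()),
                        method="model",
                    ))
                )
    else:
        triggers = engine if isinstance(engine, TriggerLexicon) else default_triggers()
        for note in notes:
            for m in extract_mentions(note, lexicon):
                out.append((note, classify_context_rules(note, m, triggers)))
    return out
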