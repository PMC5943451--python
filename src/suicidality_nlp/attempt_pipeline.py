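"""The hybrid suicide-attempt classifier.

Stages, in running order:

1. dictionary matching — every hit of the attempt-term gazetteer becomes a
   :class:`~suicidality_nlp.corpus_model.ConceptMention` with its ``match``
   text and ~500-character ``context_string``;
2. context windows — up to six sentence combinations around the concept
   sentence ({s}, {s-1,s}, {s,s+1}, {s-1,s,s+1}, {s-2..s}, {s..s+2}), clipped
   at document edges and deduplicated;
3. features — a bag of token stems and stem+POS pairs over the window, plus
   three binary assertion flags (negated / historical / experiencer-other),
   with optional stop-word removal;
4. training — a grid over {stop-word removal} x {SVM cost}, each cell scored
   by stratified k-fold cross-validated F1; the best cell is refit on all
   data and a Platt sigmoid is fitted to out-of-fold decision scores so every
   prediction carries a probability of being classified correctly;
5. prediction — each window is scored independently and the window with the
   highest calibrated confidence decides the label (ties to the smallest
   window id).  The lowest-confidence records can then be ranked out for
   manual review (active learning).

The linear SVM, vectorizer and fold logic come from scikit-learn; the model
itself is persisted as deterministic JSON (vocabulary, weights, bias,
calibration, config snapshot, training-set fingerprint).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

from .context_modifiers import ContextFlags, TriggerLexicon, apply_context, default_trigger_lexicon
from .corpus_model import (
    DEFAULT_CONTEXT_BUDGET,
    NON_TRUE_EVENT,
    TRUE_EVENT,
    ClinicalDocument,
    ConceptMention,
    Gazetteer,
    MentionClassification,
    ValidationError,
    build_context_string,
)
from .preprocess import (
    PreprocessedDocument,
    StopWordList,
    Token,
    default_stopwords,
    load_data_text,
    match_gazetteer,
    preprocess_document,
)

__all__ = [
    "WINDOW_SPECS",
    "TrainingError",
    "default_attempt_gazetteer",
    "detect_attempt_mentions",
    "build_windows",
    "extract_features",
    "MentionInstance",
    "build_instance",
    "TrainedModel",
    "train_model",
    "classify_mention",
    "rank_for_review",
]


class TrainingError(ValueError):
    """Raised when the training set cannot support model fitting."""


#: The six sentence-offset combinations around the concept sentence s.
WINDOW_SPECS: dict[int, tuple[int, ...]] = {
    1: (0,),
    2: (-1, 0),
    3: (0, 1),
    4: (-1, 0, 1),
    5: (-2, -1, 0),
    6: (0, 1, 2),
}

DEFAULT_COST_GRID = (0.1, 1.0, 10.0)


def default_attempt_gazetteer() -> Gazetteer:
    """The packaged seed dictionary of suicide-attempt surface patterns."""
    from .ideation_rules import _gazetteer_from_text

    return _gazetteer_from_text(load_data_text("attempt_terms.txt"), "attempt_terms")


# ---------------------------------------------------------------------------
# Concept detection
# ---------------------------------------------------------------------------

def detect_attempt_mentions(
    doc: ClinicalDocument | PreprocessedDocument,
    gazetteer: Gazetteer | None = None,
    context_budget: int = DEFAULT_CONTEXT_BUDGET,
) -> list[ConceptMention]:
    """One attempt mention per dictionary hit (same-span duplicates merged)."""
    if gazetteer is None:
        gazetteer = default_attempt_gazetteer()
    pre = doc if isinstance(doc, PreprocessedDocument) else preprocess_document(doc)
    document = pre.document
    mentions: list[ConceptMention] = []
    seen_spans: set[tuple[int, int]] = set()
    for sentence, tokens in zip(pre.sentences, pre.tokens):
        for hit in match_gazetteer(gazetteer, tokens):
            span = (hit.start, hit.end)
            if span in seen_spans:
                continue
            seen_spans.add(span)
            mentions.append(
                ConceptMention(
                    doc_id=document.doc_id,
                    patient_id=document.patient_id,
                    concept="attempt",
                    sentence_index=sentence.index,
                    match=document.text[hit.start : hit.end],
                    match_start=hit.start,
                    match_end=hit.end,
                    context_string=build_context_string(
                        document.text,
                        pre.sentences,
                        sentence.index,
                        hit.start,
                        hit.end,
                        context_budget,
                    ),
                )
            )
    return mentions


# ---------------------------------------------------------------------------
# Windows and features
# ---------------------------------------------------------------------------

def clip_window(spec_id: int, sentence_index: int, n_sentences: int) -> tuple[int, ...]:
    """Sentence indices of one window spec after clipping to the document."""
    return tuple(
        sentence_index + off
        for off in WINDOW_SPECS[spec_id]
        if 0 <= sentence_index + off < n_sentences
    )


def build_windows(
    sentence_index: int, n_sentences: int
) -> list[tuple[int, tuple[int, ...]]]:
    """The up-to-six distinct clipped windows for a mention sentence.

    Windows whose clipped sentence sets coincide are deduplicated, keeping
    the smallest window id.
    """
    if not 0 <= sentence_index < n_sentences:
        raise ValidationError(
            f"sentence index {sentence_index} outside document of {n_sentences} sentences"
        )
    windows: list[tuple[int, tuple[int, ...]]] = []
    seen: set[tuple[int, ...]] = set()
    for wid in sorted(WINDOW_SPECS):
        indices = clip_window(wid, sentence_index, n_sentences)
        if indices and indices not in seen:
            seen.add(indices)
            windows.append((wid, indices))
    return windows


def extract_features(
    window_tokens: Sequence[Token],
    flags: ContextFlags | None = None,
    remove_stopwords: bool = False,
    stopwords: StopWordList | None = None,
) -> dict[str, int]:
    """Bag-of-words counts over stems and stem+POS pairs, plus flag bits."""
    if remove_stopwords and stopwords is None:
        stopwords = default_stopwords()
    feats: dict[str, int] = {}
    for tok in window_tokens:
        if remove_stopwords and tok.surface in stopwords:
            continue
        feats[tok.stem] = feats.get(tok.stem, 0) + 1
        pair = f"{tok.stem}|{tok.pos}"
        feats[pair] = feats.get(pair, 0) + 1
    if flags is not None:
        if flags.negated:
            feats["CTX:negated"] = 1
        if flags.historical:
            feats["CTX:historical"] = 1
        if flags.experiencer_other:
            feats["CTX:experiencer_other"] = 1
    return feats


@dataclass
class MentionInstance:
    """A mention prepared for learning: windows of tagged tokens + flags."""

    mention: ConceptMention
    windows: list[tuple[int, list[Token]]]
    flags: ContextFlags
    n_sentences: int

    @property
    def key(self):
        return self.mention.key

    def window_tokens(self, wid: int) -> list[Token]:
        for w, toks in self.windows:
            if w == wid:
                return toks
        # The requested spec may have been deduplicated into a smaller id;
        # rebuild its clipped sentence set from the stored windows.
        indices = clip_window(wid, self.mention.sentence_index, self.n_sentences)
        by_index: dict[int, list[Token]] = {}
        for _w, toks in self.windows:
            for tok in toks:
                bucket = by_index.setdefault(tok.sentence_index, [])
                if not bucket or bucket[-1] is not tok:
                    if tok not in bucket:
                        bucket.append(tok)
        flat: list[Token] = []
        for i in indices:
            flat.extend(by_index.get(i, []))
        return flat


def build_instance(
    pre: PreprocessedDocument,
    mention: ConceptMention,
    lexicon: TriggerLexicon | None = None,
) -> MentionInstance:
    """Assemble windows and assertion flags for one detected mention."""
    if lexicon is None:
        lexicon = default_trigger_lexicon()
    n = len(pre.sentences)
    sent_tokens = pre.sentence_tokens(mention.sentence_index)
    tok_range = _mention_token_range(sent_tokens, mention)
    flags = apply_context(tok_range, sent_tokens, lexicon)
    windows = []
    for wid, indices in build_windows(mention.sentence_index, n):
        flat: list[Token] = []
        for i in indices:
            flat.extend(pre.sentence_tokens(i))
        windows.append((wid, flat))
    return MentionInstance(mention=mention, windows=windows, flags=flags, n_sentences=n)


def _mention_token_range(tokens: Sequence[Token], mention: ConceptMention) -> tuple[int, int]:
    idx = [
        i
        for i, t in enumerate(tokens)
        if t.start < mention.match_end and mention.match_start < t.end
    ]
    if not idx:
        return (0, 0)
    return (idx[0], idx[-1] + 1)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A linear SVM with vocabulary, Platt calibration and config snapshot."""

    feature_names: list[str]
    weights: list[float]
    bias: float
    platt_a: float
    platt_b: float
    remove_stopwords: bool
    cost: float
    train_window_id: int
    fingerprint: str
    cv_report: dict = field(default_factory=dict)
    version: int = 1

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.weights):
            raise ValidationError("vocabulary does not cover the weight vector")
        self._wmap = dict(zip(self.feature_names, self.weights))

    def decision(self, features: dict[str, int]) -> float:
        return sum(self._wmap.get(f, 0.0) * v for f, v in features.items()) + self.bias

    def proba_true(self, features: dict[str, int]) -> float:
        """Calibrated probability that the instance is a true event."""
        f = self.decision(features)
        return 1.0 / (1.0 + math.exp(self.platt_a * f + self.platt_b))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "feature_names": self.feature_names,
            "weights": self.weights,
            "bias": self.bias,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "remove_stopwords": self.remove_stopwords,
            "cost": self.cost,
            "train_window_id": self.train_window_id,
            "fingerprint": self.fingerprint,
            "cv_report": self.cv_report,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        version = payload.pop("version", 1)
        return cls(version=version, **payload)


def _platt_fit(scores: np.ndarray, y: np.ndarray, max_iter: int = 200) -> tuple[float, float]:
    """Platt sigmoid p=1/(1+exp(A*f+B)) by the Lin-Weng-Keerthi Newton method."""
    prior1 = float(np.sum(y == 1))
    prior0 = float(len(y) - prior1)
    hi_t = (prior1 + 1.0) / (prior1 + 2.0)
    lo_t = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi_t, lo_t)
    a, b = 0.0, math.log((prior0 + 1.0) / (prior1 + 1.0))
    f = scores.astype(float)

    def objective(a_, b_):
        fab = a_ * f + b_
        return float(
            np.sum(np.where(fab >= 0, t * fab + np.log1p(np.exp(-fab)),
                            (t - 1) * fab + np.log1p(np.exp(fab))))
        )

    fval = objective(a, b)
    sigma, min_step = 1e-12, 1e-10
    for _ in range(max_iter):
        fab = a * f + b
        p = np.where(fab >= 0, np.exp(-fab) / (1 + np.exp(-fab)), 1 / (1 + np.exp(fab)))
        q = 1 - p
        d1 = t - p
        d2 = p * q
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            new_a, new_b = a + step * dA, b + step * dB
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            break
    return a, b


def _index32(X):
    # liblinear requires 32-bit sparse indices; DictVectorizer emits 64-bit.
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


def _make_pipeline(cost: float, seed: int) -> Pipeline:
    from sklearn.preprocessing import FunctionTransformer

    return Pipeline(
        [
            ("vec", DictVectorizer()),
            ("idx32", FunctionTransformer(_index32, accept_sparse=True)),
            (
                "svm",
                LinearSVC(C=cost, random_state=seed, max_iter=20000, tol=1e-4),
            ),
        ]
    )


def train_model(
    instances: Sequence[MentionInstance],
    labels: Sequence[str],
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    k: int = 5,
    seed: int = 0,
    train_window_id: int = 4,
    stopwords: StopWordList | None = None,
) -> TrainedModel:
    """Grid-search {stop-word removal} x {cost} by k-fold CV F1, refit best.

    Deterministic for a fixed seed: fold assignment, grid order and
    tie-breaking (first best cell in grid order) are all fixed.
    """
    if len(instances) != len(labels):
        raise ValidationError("instances and labels differ in length")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if not cost_grid:
        raise ValidationError("empty cost grid")
    y = np.array([1 if lab == TRUE_EVENT else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise TrainingError("training set contains a single class")
    if stopwords is None:
        stopwords = default_stopwords()

    feature_cache: dict[bool, list[dict[str, int]]] = {}
    for rm in (False, True):
        feature_cache[rm] = [
            extract_features(
                inst.window_tokens(train_window_id), inst.flags, rm, stopwords
            )
            for inst in instances
        ]

    n_splits = min(k, int(np.min(np.bincount(y))))
    if n_splits < 2:
        raise TrainingError("too few instances of the minority class for CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    results = []
    for rm in (False, True):
        for cost in cost_grid:
            pipe = _make_pipeline(cost, seed)
            scores = cross_val_score(pipe, feature_cache[rm], y, cv=skf, scoring="f1")
            results.append(
                {
                    "remove_stopwords": rm,
                    "cost": float(cost),
                    "cv_f1_mean": float(np.mean(scores)),
                    "cv_f1_per_fold": [float(s) for s in scores],
                }
            )
    best = max(results, key=lambda r: r["cv_f1_mean"])  # ties -> first in order

    X = feature_cache[best["remove_stopwords"]]
    pipe = _make_pipeline(best["cost"], seed)
    oof_scores = cross_val_predict(pipe, X, y, cv=skf, method="decision_function")
    platt_a, platt_b = _platt_fit(np.asarray(oof_scores), y)
    pipe.fit(X, y)
    vec: DictVectorizer = pipe.named_steps["vec"]
    svm: LinearSVC = pipe.named_steps["svm"]

    digest = hashlib.sha256()
    for feats, lab in zip(X, labels):
        digest.update(json.dumps([sorted(feats.items()), lab]).encode())
    fingerprint = digest.hexdigest()

    return TrainedModel(
        feature_names=list(vec.feature_names_),
        weights=[float(w) for w in svm.coef_.ravel()],
        bias=float(svm.intercept_[0]),
        platt_a=float(platt_a),
        platt_b=float(platt_b),
        remove_stopwords=bool(best["remove_stopwords"]),
        cost=float(best["cost"]),
        train_window_id=train_window_id,
        fingerprint=fingerprint,
        cv_report={"grid": results, "selected": best, "n_splits": n_splits},
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def classify_mention(
    model: TrainedModel,
    instance: MentionInstance,
    stopwords: StopWordList | None = None,
) -> MentionClassification:
    """Score every window; the highest-confidence window decides the label.

    Per window the calibrated probability of ``true_event`` is p; the window
    votes ``true_event`` when p >= 0.5 with confidence max(p, 1-p).  Ties go
    to the smallest window id.
    """
    if not model.feature_names:
        raise ValidationError("model vocabulary is empty")
    if model.remove_stopwords and stopwords is None:
        stopwords = default_stopwords()
    best: tuple[float, int, str] | None = None
    for wid, tokens in instance.windows:
        feats = extract_features(tokens, instance.flags, model.remove_stopwords, stopwords)
        p = model.proba_true(feats)
        label = TRUE_EVENT if p >= 0.5 else NON_TRUE_EVENT
        conf = max(p, 1.0 - p)
        if best is None or conf > best[0]:
            best = (conf, wid, label)
    assert best is not None
    conf, wid, label = best
    return MentionClassification(
        key=instance.key, label=label, confidence=conf, window_used=wid
    )


def rank_for_review(
    classifications: Sequence[MentionClassification], n: int
) -> list[MentionClassification]:
    """The n lowest-confidence classifications, ascending, stable for ties."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    return sorted(classifications, key=lambda c: c.confidence)[:n]
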