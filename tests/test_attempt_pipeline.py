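import random

import pytest

from suicidality_nlp import (
    NON_TRUE_EVENT,
    TRUE_EVENT,
    MentionClassification,
    TrainedModel,
    TrainingError,
    WINDOW_SPECS,
    build_instance,
    build_windows,
    classify_mention,
    detect_attempt_mentions,
    extract_features,
    generate_planted_keyword_corpus,
    preprocess_document,
    rank_for_review,
    train_model,
)
from suicidality_nlp.context_modifiers import ContextFlags
from suicidality_nlp.corpus_model import ValidationError

from _helpers import make_tokens
from suicidality_nlp.preprocess import pos_tag


class TestDetection:
    def test_overdose_and_attempt_in_one_sentence(self, preprocessed_factory, attempt_gazetteer):
        pre = preprocessed_factory("took an overdose in a suicide attempt")
        matches = {m.match for m in detect_attempt_mentions(pre, attempt_gazetteer)}
        assert matches == {"overdose", "suicide attempt"}

    def test_heading_detected_filtering_is_downstream(self, preprocessed_factory, attempt_gazetteer):
        pre = preprocessed_factory("History of previous suicide attempts")
        mentions = detect_attempt_mentions(pre, attempt_gazetteer)
        assert len(mentions) == 1
        assert mentions[0].match == "suicide attempts"

    def test_document_without_terms(self, preprocessed_factory, attempt_gazetteer):
        pre = preprocessed_factory("Seen at the clinic today. Mood stable.")
        assert detect_attempt_mentions(pre, attempt_gazetteer) == []


class TestWindows:
    def test_middle_of_five_sentences_gives_six_windows(self):
        windows = build_windows(2, 5)
        assert len(windows) == 6
        assert dict(windows) == {
            1: (2,), 2: (1, 2), 3: (2, 3), 4: (1, 2, 3), 5: (0, 1, 2), 6: (2, 3, 4)
        }

    def test_single_sentence_document_collapses_to_one(self):
        assert build_windows(0, 1) == [(1, (0,))]

    def test_first_sentence_of_long_document(self):
        # enumerating the six specs at s=0 and deduplicating the clipped sets:
        clipped = {tuple(0 + o for o in offs if 0 <= 0 + o < 10) for offs in WINDOW_SPECS.values()}
        windows = build_windows(0, 10)
        assert {idx for _w, idx in windows} == clipped
        assert len(windows) == 3

    def test_every_window_contains_the_concept_sentence(self):
        for s, n in [(0, 4), (3, 4), (2, 9)]:
            for _wid, indices in build_windows(s, n):
                assert s in indices

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            build_windows(4, 4)


class TestFeatures:
    def test_hand_enumerated_bag(self, stopwords):
        toks = pos_tag(make_tokens(["she", "attempted", "it"]))
        feats = extract_features(toks, ContextFlags())
        assert feats == {
            "she": 1, "she|PRP": 1,
            "attempt": 1, "attempt|VBD": 1,
            "it": 1, "it|PRP": 1,
        }

    def test_stopword_removal(self, stopwords):
        toks = pos_tag(make_tokens(["she", "attempted", "it"]))
        feats = extract_features(toks, None, remove_stopwords=True, stopwords=stopwords)
        assert set(feats) == {"attempt", "attempt|VBD"}

    def test_flag_indicator_features(self):
        flags = ContextFlags(negated=True, historical=True)
        feats = extract_features([], flags)
        assert feats == {"CTX:negated": 1, "CTX:historical": 1}

    def test_deterministic(self):
        toks = pos_tag(make_tokens(["overdose", "of", "paracetamol"]))
        assert extract_features(toks, None) == extract_features(toks, None)


def _instances(n=160, seed=3):
    docs, labels = generate_planted_keyword_corpus(n=n, seed=seed)
    insts = []
    for doc in docs:
        pre = preprocess_document(doc)
        (mention,) = detect_attempt_mentions(pre)
        insts.append(build_instance(pre, mention))
    return insts, labels


class TestTraining:
    def test_separable_corpus_reaches_high_heldout_f1(self):
        insts, labels = _instances(n=200, seed=11)
        model = train_model(insts[:140], labels[:140], seed=11)
        correct = sum(
            classify_mention(model, inst).label == lab
            for inst, lab in zip(insts[140:], labels[140:])
        )
        assert correct >= 0.95 * 60

    def test_single_class_training_set_errors(self):
        insts, labels = _instances(n=30, seed=1)
        with pytest.raises(TrainingError):
            train_model(insts, [TRUE_EVENT] * len(insts), seed=1)

    def test_duplicated_training_set_selects_same_hyperparameters(self):
        insts, labels = _instances(n=80, seed=5)
        m1 = train_model(insts, labels, seed=5)
        m2 = train_model(insts + insts, labels + labels, seed=5)
        assert (m1.cost, m1.remove_stopwords) == (m2.cost, m2.remove_stopwords)

    def test_seeded_training_is_reproducible(self, tmp_path):
        insts, labels = _instances(n=80, seed=5)
        m1 = train_model(insts, labels, seed=5)
        m2 = train_model(insts, labels, seed=5)
        assert m1.fingerprint == m2.fingerprint
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        m1.save(p1)
        m2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_model_reloads_identically(self, tmp_path):
        insts, labels = _instances(n=80, seed=5)
        model = train_model(insts, labels, seed=5)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = TrainedModel.load(path)
        path2 = tmp_path / "model2.json"
        reloaded.save(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_planted_keyword_gets_top_decile_weight(self):
        insts, labels = _instances(n=250, seed=17)
        model = train_model(insts, labels, seed=17)
        magnitudes = sorted(abs(w) for w in model.weights)
        cutoff = magnitudes[int(0.9 * len(magnitudes))]
        kw_weight = abs(dict(zip(model.feature_names, model.weights))["lorazepam"])
        assert kw_weight >= cutoff

    def test_empty_grid_rejected(self):
        insts, labels = _instances(n=30, seed=2)
        with pytest.raises(ValidationError):
            train_model(insts, labels, cost_grid=(), seed=2)


class TestClassification:
    def test_unseen_vocabulary_uses_bias_without_error(self):
        insts, labels = _instances(n=80, seed=5)
        model = train_model(insts, labels, seed=5)
        from suicidality_nlp import ClinicalDocument

        pre = preprocess_document(
            ClinicalDocument("z", "pz", "event", "xyzzy qwerty suicide attempt plugh")
        )
        (mention,) = detect_attempt_mentions(pre)
        inst = build_instance(pre, mention)
        result = classify_mention(model, inst)
        assert 0.0 <= result.confidence <= 1.0
        assert result.label in (TRUE_EVENT, NON_TRUE_EVENT)

    def test_tie_breaks_to_smallest_window_id(self):
        model = TrainedModel(
            feature_names=["attempt"], weights=[0.0], bias=0.4,
            platt_a=-1.0, platt_b=0.0, remove_stopwords=False, cost=1.0,
            train_window_id=4, fingerprint="x",
        )
        from suicidality_nlp import ClinicalDocument

        pre = preprocess_document(
            ClinicalDocument("d", "p", "event", "One line.\nA suicide attempt here.\nMore text.")
        )
        (mention,) = detect_attempt_mentions(pre)
        inst = build_instance(pre, mention)
        result = classify_mention(model, inst)
        assert result.window_used == 1  # all windows score identically

    def test_confidence_is_max_over_windows(self):
        insts, labels = _instances(n=80, seed=5)
        model = train_model(insts, labels, seed=5)
        inst = insts[0]
        per_window = []
        from suicidality_nlp.attempt_pipeline import extract_features as ef

        for _wid, toks in inst.windows:
            p = model.proba_true(ef(toks, inst.flags, model.remove_stopwords))
            per_window.append(max(p, 1 - p))
        assert classify_mention(model, inst).confidence == pytest.approx(max(per_window))


class TestReviewRanking:
    def _cls(self, conf, key):
        return MentionClassification(key=(key, 0, 1), label=TRUE_EVENT, confidence=conf)

    def test_lowest_confidence_first(self):
        items = [self._cls(0.9, "a"), self._cls(0.51, "b"), self._cls(0.99, "c")]
        assert [c.key[0] for c in rank_for_review(items, 1)] == ["b"]

    def test_n_zero_and_n_beyond_count(self):
        items = [self._cls(0.7, "a"), self._cls(0.6, "b")]
        assert rank_for_review(items, 0) == []
        assert len(rank_for_review(items, 10)) == 2

    def test_stable_for_ties(self):
        items = [self._cls(0.5, "first"), self._cls(0.5, "second")]
        assert [c.key[0] for c in rank_for_review(items, 2)] == ["first", "second"]

    def test_negative_n_rejected(self):
        with pytest.raises(ValidationError):
            rank_for_review([], -1)
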