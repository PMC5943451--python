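import pytest

from suicidality_nlp import (
    ClinicalDocument,
    ConceptMention,
    ConfusionMatrix,
    MentionClassification,
    build_context_string,
    read_corpus,
    read_gazetteer,
    read_results,
    split_sentences,
    write_corpus,
    write_results,
)
from suicidality_nlp.corpus_model import (
    RESULT_COLUMNS,
    ConsistencyError,
    GazetteerEntry,
    SchemaError,
    ValidationError,
)


class TestCorpusIO:
    def test_jsonl_two_doc_types(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"doc_id": "a", "patient_id": "p1", "doc_type": "event", "text": "note"}\n'
            '{"doc_id": "b", "patient_id": "p2", "doc_type": "correspondence", "text": "letter"}\n'
        )
        docs = read_corpus(path)
        assert [d.doc_id for d in docs] == ["a", "b"]
        assert {d.doc_type for d in docs} == {"event", "correspondence"}

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_corpus(path) == []

    def test_missing_patient_id_is_schema_error_naming_record(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"doc_id": "a", "patient_id": "p", "doc_type": "event", "text": "t"}\n'
            '{"doc_id": "b", "doc_type": "event", "text": "t"}\n'
        )
        with pytest.raises(SchemaError, match="record 1.*patient_id"):
            read_corpus(path)

    def test_unknown_doc_type_rejected(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text('{"doc_id": "a", "patient_id": "p", "doc_type": "referral", "text": "t"}\n')
        with pytest.raises(ValidationError, match="doc_type"):
            read_corpus(path)

    def test_duplicate_doc_id_rejected(self, tmp_path):
        path = tmp_path / "c.jsonl"
        rec = '{"doc_id": "a", "patient_id": "p", "doc_type": "event", "text": "t"}\n'
        path.write_text(rec + rec)
        with pytest.raises(ValidationError, match="duplicate"):
            read_corpus(path)

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_roundtrip_identity_including_newlines(self, tmp_path, fmt):
        docs = [
            ClinicalDocument("a", "p1", "event", "line one\nPast suicide attempts\nline 3", "2015-02-01"),
            ClinicalDocument("b", "p2", "correspondence", 'quoted "text", with commas'),
        ]
        path = tmp_path / f"c.{fmt}"
        write_corpus(docs, path, format=fmt)
        back = read_corpus(path, format=fmt)
        assert [(d.doc_id, d.patient_id, d.doc_type, d.text, d.date) for d in back] == [
            (d.doc_id, d.patient_id, d.doc_type, d.text, d.date) for d in docs
        ]


class TestGazetteer:
    def test_wildcard_pattern_line(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("suicid* ideat*\n")
        gaz = read_gazetteer(path)
        assert len(gaz.entries) == 1
        assert gaz.entries[0].tokens == ("suicid*", "ideat*")
        assert gaz.case_policy == "fold"

    def test_blank_and_comment_lines_only(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("# a comment\n\n   \n")
        assert read_gazetteer(path).entries == []

    def test_literal_multiword_pattern(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("attempt to end her life\n")
        entry = read_gazetteer(path).entries[0]
        assert entry.tokens == ("attempt", "to", "end", "her", "life")
        assert not any(t.endswith("*") for t in entry.tokens)

    def test_lone_star_rejected(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("attempt *\n")
        with pytest.raises(ValidationError, match="lone"):
            read_gazetteer(path)

    def test_interior_star_rejected(self):
        with pytest.raises(ValidationError):
            GazetteerEntry(("sui*de",), "sui*de")

    def test_case_policy_directive(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("# case_policy: exact\nICD\n")
        assert read_gazetteer(path).case_policy == "exact"


def _mention(context="ctx around the match", match="suicide attempt"):
    return ConceptMention(
        doc_id="d1",
        patient_id="p1",
        concept="attempt",
        sentence_index=0,
        match=match,
        match_start=4,
        match_end=4 + len(match),
        context_string=context,
    )


class TestResultsIO:
    def test_single_row_has_required_columns(self, tmp_path):
        m = _mention()
        cls = MentionClassification(key=m.key, label="true_event", confidence=0.9, window_used=1)
        path = tmp_path / "r.csv"
        write_results([m], [cls], path)
        header = path.read_text().splitlines()[0].split(",")
        for col in ["doc_id", "patient_id", "concept", "match", "context_string", "label", "confidence"]:
            assert col in header
        assert header == RESULT_COLUMNS

    def test_roundtrip_identity(self, tmp_path):
        m = _mention(context="multi\nline context, with commas")
        cls = MentionClassification(key=m.key, label="non_true_event", confidence=0.625, window_used=3)
        path = tmp_path / "r.csv"
        write_results([m], [cls], path, config={"stage": "test"})
        mentions, classifications = read_results(path)
        assert mentions == [m]
        assert classifications == [cls]

    def test_unkeyed_classification_rejected(self, tmp_path):
        m = _mention()
        stray = MentionClassification(key=("other", 0, 1), label="true_event", confidence=0.5)
        with pytest.raises(ConsistencyError):
            write_results([m], [stray], tmp_path / "r.csv")

    def test_context_budget_is_honored_in_output(self, tmp_path, preprocessed_factory):
        text = " ".join(f"Sentence number {i} talks about a suicide attempt event." for i in range(40))
        pre = preprocessed_factory(text)
        idx = text.index("suicide attempt")
        ctx = build_context_string(text, pre.sentences, 0, idx, idx + 15, budget=500)
        m = _mention(context=ctx)
        cls = MentionClassification(key=m.key, label="true_event", confidence=1.0)
        path = tmp_path / "r.csv"
        write_results([m], [cls], path)
        (read_m,), _ = read_results(path)
        assert len(read_m.context_string) <= 500


class TestContextString:
    def test_budget_never_exceeded_and_match_kept(self, preprocessed_factory):
        text = "\n".join(f"Line {i} of a long clinical note with some words." for i in range(30))
        pre = preprocessed_factory(text)
        target = pre.sentences[15]
        for budget in (40, 120, 500, 10_000):
            ctx = build_context_string(
                text, pre.sentences, 15, target.start, target.start + 6, budget=budget
            )
            assert len(ctx) <= budget
            if budget >= len(target.text):
                assert "Line 15" in ctx

    def test_whole_sentences_accumulate_nearest_first(self, preprocessed_factory):
        text = "First sentence here. Second one with the match. Third sentence follows."
        pre = preprocessed_factory(text)
        idx = text.index("match")
        ctx = build_context_string(text, pre.sentences, 1, idx, idx + 5, budget=len(text) + 10)
        assert ctx == text  # everything fits

    def test_zero_sentences_degenerate(self):
        assert build_context_string("abcdef", [], 0, 1, 3, budget=10) == "bc"


class TestConfusionMatrix:
    def test_total_is_sum_of_cells(self):
        cm = ConfusionMatrix(a=265, b=37, c=24, d=174)
        assert cm.n == 500

    @pytest.mark.parametrize("bad", [{"a": -1}, {"b": 1.5}])
    def test_invalid_counts_rejected(self, bad):
        base = dict(a=1, b=1, c=1, d=1)
        base.update(bad)
        with pytest.raises(ValidationError):
            ConfusionMatrix(**base)
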