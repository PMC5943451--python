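"""Domain types and file I/O for clinical-note corpora, gazetteers and results.

The package operates on pseudonymised free-text psychiatric documents of two
kinds: *event* notes (day-to-day free text in any layout) and *correspondence*
notes (letters and questionnaires attached to the record).  Everything
downstream — sentence splitting, dictionary matching, the ideation rules and
the attempt classifier — works in terms of the types defined here.

Character offsets are 0-based half-open throughout the package.  Corpus
interchange is JSONL (one document per line, so embedded newlines survive),
with CSV as a secondary format.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DOC_TYPES",
    "CONCEPTS",
    "LABELS",
    "TRUE_EVENT",
    "NON_TRUE_EVENT",
    "SchemaError",
    "ValidationError",
    "ConsistencyError",
    "ClinicalDocument",
    "Sentence",
    "Token",
    "Gazetteer",
    "GazetteerEntry",
    "ConceptMention",
    "GoldAnnotation",
    "ConfusionMatrix",
    "MentionClassification",
    "read_corpus",
    "write_corpus",
    "read_gazetteer",
    "write_gazetteer",
    "read_results",
    "write_results",
    "build_context_string",
]

DOC_TYPES = ("event", "correspondence")
CONCEPTS = ("ideation", "attempt")
TRUE_EVENT = "true_event"
NON_TRUE_EVENT = "non_true_event"
LABELS = (TRUE_EVENT, NON_TRUE_EVENT)

#: Default size (characters) of the context excerpt stored with each mention.
DEFAULT_CONTEXT_BUDGET = 500


class SchemaError(ValueError):
    """A record is missing a required field or has a malformed value."""


class ValidationError(ValueError):
    """An input violates a documented invariant (e.g. a bad wildcard pattern)."""


class ConsistencyError(ValueError):
    """Cross-referenced objects do not line up (e.g. unkeyed classification)."""


# ---------------------------------------------------------------------------
# Documents and text substrate
# ---------------------------------------------------------------------------

@dataclass
class ClinicalDocument:
    """One free-text clinical document.

    ``doc_type`` is ``"event"`` (day-to-day progress note) or
    ``"correspondence"`` (letter/questionnaire attachment).  ``text`` may be
    empty but never absent; ``date`` is an optional ISO-8601 date string.
    """

    doc_id: str
    patient_id: str
    doc_type: str
    text: str
    date: str | None = None

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValidationError(
                f"doc_type must be one of {DOC_TYPES}, got {self.doc_type!r}"
            )


@dataclass(frozen=True)
class Sentence:
    """A sentence with its exact character span into the parent document."""

    doc_id: str
    index: int
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Token:
    """A token with document-level character offsets, stem and POS tag."""

    sentence_index: int
    start: int
    end: int
    surface: str
    stem: str = ""
    pos: str = ""


# ---------------------------------------------------------------------------
# Gazetteers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazetteerEntry:
    """One dictionary pattern: a token sequence, tokens may end in ``*``.

    A terminal ``*`` makes the token a prefix wildcard ("suicid*" matches
    "suicide", "suicidal", ...).  ``raw`` preserves the source line.
    """

    tokens: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError("empty gazetteer pattern")
        for tok in self.tokens:
            if tok == "*":
                raise ValidationError(
                    f"pattern {self.raw!r}: lone '*' (wildcard needs a prefix)"
                )
            if "*" in tok[:-1]:
                raise ValidationError(
                    f"pattern {self.raw!r}: '*' is only allowed token-terminally"
                )


@dataclass
class Gazetteer:
    """A named list of surface patterns used for dictionary matching."""

    name: str
    entries: list[GazetteerEntry] = field(default_factory=list)
    case_policy: str = "fold"  # "fold" or "exact"

    def __post_init__(self) -> None:
        if self.case_policy not in ("fold", "exact"):
            raise ValidationError(f"unknown case_policy {self.case_policy!r}")


def read_gazetteer(path, name: str | None = None) -> Gazetteer:
    """Read a plain-text gazetteer: one pattern per line, ``#`` comments.

    A comment of the form ``# case_policy: exact`` switches off case folding
    for the whole file (the default policy is ``fold``).
    """
    case_policy = "fold"
    entries: list[GazetteerEntry] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                directive = stripped.lstrip("#").strip().lower()
                if directive.replace(" ", "").startswith(("case_policy:", "case:")):
                    case_policy = directive.split(":", 1)[1].strip()
                continue
            entries.append(GazetteerEntry(tuple(stripped.split()), stripped))
    import os

    return Gazetteer(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        entries=entries,
        case_policy=case_policy,
    )


def write_gazetteer(gaz: Gazetteer, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if gaz.case_policy != "fold":
            fh.write(f"# case_policy: {gaz.case_policy}\n")
        for entry in gaz.entries:
            fh.write(entry.raw + "\n")


# ---------------------------------------------------------------------------
# Mentions, gold labels, classifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptMention:
    """A dictionary/pattern hit inside one sentence of a document.

    ``match`` is the exact matched text; ``context_string`` is an excerpt of
    up to the configured budget (about 500 characters by default) centred on
    the match, built from the whole sentences nearest to it.
    """

    doc_id: str
    patient_id: str
    concept: str
    sentence_index: int
    match: str
    match_start: int
    match_end: int
    context_string: str

    @property
    def key(self) -> tuple[str, int, int]:
        """Stable mention key: (doc_id, match_start, match_end)."""
        return (self.doc_id, self.match_start, self.match_end)


@dataclass(frozen=True)
class GoldAnnotation:
    """A manual binary label for one instance (mention- or sentence-keyed)."""

    key: tuple
    label: str
    annotator_id: str = "gold"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be in {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts, classifier rows x gold columns.

    ``a`` classifier-true & gold-true, ``b`` classifier-false & gold-true,
    ``c`` classifier-true & gold-false, ``d`` classifier-false & gold-false.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"confusion count {name} must be a non-negative int")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class MentionClassification:
    """A classifier decision for one mention, with calibrated confidence."""

    key: tuple
    label: str
    confidence: float
    window_used: int = 0

    def relabelled(self, label: str) -> "MentionClassification":
        return replace(self, label=label)


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("doc_id", "patient_id", "doc_type", "text")


def _document_from_record(record: Mapping, recno: int) -> ClinicalDocument:
    for fieldname in _REQUIRED_FIELDS:
        if fieldname not in record or record[fieldname] is None:
            raise SchemaError(f"record {recno}: missing required field {fieldname!r}")
    doc_type = str(record["doc_type"])
    if doc_type not in DOC_TYPES:
        raise ValidationError(
            f"record {recno}: unknown doc_type {doc_type!r} (expected one of {DOC_TYPES})"
        )
    date = record.get("date")
    return ClinicalDocument(
        doc_id=str(record["doc_id"]),
        patient_id=str(record["patient_id"]),
        doc_type=doc_type,
        text=str(record["text"]),
        date=str(date) if date not in (None, "") else None,
    )


def read_corpus(path, format: str = "jsonl") -> list[ClinicalDocument]:
    """Read documents from JSONL (default) or CSV, order preserved."""
    docs: list[ClinicalDocument] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for recno, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"record {recno}: invalid JSON ({exc})") from exc
                docs.append(_document_from_record(record, recno))
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            for recno, record in enumerate(reader):
                docs.append(_document_from_record(record, recno))
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {doc.doc_id!r} in corpus")
        seen.add(doc.doc_id)
    return docs


def write_corpus(docs: Iterable[ClinicalDocument], path, format: str = "jsonl") -> None:
    docs = list(docs)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for doc in docs:
                record = {
                    "doc_id": doc.doc_id,
                    "patient_id": doc.patient_id,
                    "doc_type": doc.doc_type,
                    "text": doc.text,
                }
                if doc.date is not None:
                    record["date"] = doc.date
                fh.write(json.dumps(record, ensure_ascii=False, sort_keys=True) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["doc_id", "patient_id", "doc_type", "text", "date"]
            )
            writer.writeheader()
            for doc in docs:
                writer.writerow(
                    {
                        "doc_id": doc.doc_id,
                        "patient_id": doc.patient_id,
                        "doc_type": doc.doc_type,
                        "text": doc.text,
                        "date": doc.date or "",
                    }
                )
    else:
        raise ValidationError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Results I/O
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "doc_id",
    "patient_id",
    "concept",
    "sentence_index",
    "match",
    "match_start",
    "match_end",
    "context_string",
    "label",
    "confidence",
    "window_used",
]


def write_results(
    mentions: Sequence[ConceptMention],
    classifications: Sequence[MentionClassification],
    path,
    format: str = "csv",
    config: Mapping | None = None,
) -> None:
    """Write classified mentions as a delimited table.

    Every classification must be keyed to a supplied mention.  When ``config``
    is given it is echoed into a leading ``#`` comment line so any output can
    be regenerated from its recorded configuration.
    """
    by_key = {m.key: m for m in mentions}
    orphans = [c.key for c in classifications if c.key not in by_key]
    if orphans:
        raise ConsistencyError(f"classifications without a mention: {orphans[:5]}")
    delimiter = {"csv": ",", "tsv": "\t"}.get(format)
    if delimiter is None:
        raise ValidationError(f"unknown results format {format!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write("# config: " + json.dumps(dict(config), sort_keys=True) + "\n")
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS, delimiter=delimiter)
        writer.writeheader()
        for cls in classifications:
            m = by_key[cls.key]
            writer.writerow(
                {
                    "doc_id": m.doc_id,
                    "patient_id": m.patient_id,
                    "concept": m.concept,
                    "sentence_index": m.sentence_index,
                    "match": m.match,
                    "match_start": m.match_start,
                    "match_end": m.match_end,
                    "context_string": m.context_string,
                    "label": cls.label,
                    "confidence": repr(float(cls.confidence)),
                    "window_used": cls.window_used,
                }
            )


def read_results(path, format: str = "csv"):
    """Read a results table back into (mentions, classifications)."""
    delimiter = {"csv": ",", "tsv": "\t"}.get(format)
    if delimiter is None:
        raise ValidationError(f"unknown results format {format!r}")
    with open(path, encoding="utf-8", newline="") as fh:
        content = fh.read()
    # Skip leading comment lines (config echo).
    lines = content.splitlines(keepends=True)
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    reader = csv.DictReader(io.StringIO("".join(lines[start:])), delimiter=delimiter)
    mentions: list[ConceptMention] = []
    classifications: list[MentionClassification] = []
    for row in reader:
        mention = ConceptMention(
            doc_id=row["doc_id"],
            patient_id=row["patient_id"],
            concept=row["concept"],
            sentence_index=int(row["sentence_index"]),
            match=row["match"],
            match_start=int(row["match_start"]),
            match_end=int(row["match_end"]),
            context_string=row["context_string"],
        )
        mentions.append(mention)
        classifications.append(
            MentionClassification(
                key=mention.key,
                label=row["label"],
                confidence=float(row["confidence"]),
                window_used=int(row["window_used"]),
            )
        )
    return mentions, classifications


# ---------------------------------------------------------------------------
# Context excerpts
# ---------------------------------------------------------------------------

def build_context_string(
    text: str,
    sentences: Sequence[Sentence],
    sentence_index: int,
    match_start: int,
    match_end: int,
    budget: int = DEFAULT_CONTEXT_BUDGET,
) -> str:
    """Build the ~``budget``-character excerpt around a match.

    Whole sentences nearest the match sentence are accumulated (expanding
    alternately to whichever neighbouring sentence is closer in character
    distance) until adding one would exceed the budget, or until one sentence
    alone exceeds it; the final excerpt is then hard-truncated to ``budget``
    characters centred on the match.
    """
    if budget <= 0:
        return ""
    if not sentences:
        return text[match_start:match_end][:budget]
    lo = hi = sentence_index
    span_start, span_end = sentences[lo].start, sentences[hi].end

    def length(s: int, e: int) -> int:
        return e - s

    mid = (match_start + match_end) // 2
    while True:
        prev_ok = lo > 0
        next_ok = hi < len(sentences) - 1
        if not prev_ok and not next_ok:
            break
        if prev_ok and next_ok:
            dist_prev = mid - sentences[lo - 1].end
            dist_next = sentences[hi + 1].start - mid
            take_prev = dist_prev <= dist_next
        else:
            take_prev = prev_ok
        if take_prev:
            cand = (sentences[lo - 1].start, span_end)
        else:
            cand = (span_start, sentences[hi + 1].end)
        if length(*cand) > budget:
            break
        span_start, span_end = cand
        if take_prev:
            lo -= 1
        else:
            hi += 1
    excerpt_start, excerpt_end = span_start, span_end
    if length(excerpt_start, excerpt_end) > budget:
        # Hard truncation centred on the match, clipped to the sentence span.
        half = budget // 2
        excerpt_start = max(span_start, min(mid - half, span_end - budget))
        excerpt_end = excerpt_start + budget
    return text[excerpt_start:excerpt_end]
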