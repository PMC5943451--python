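"""The rule-based suicide-ideation classifier.

Detection is deliberately simple: a sentence containing a token matching
``suicid*`` and a token matching ``ideat*`` (the standard clinical phrase
"suicidal ideation" and its variants) yields one ideation mention.  The
classification rule is a sentence-scope veto: if any entry of either
negation gazetteer occurs in the sentence, the mention is labelled
``non_true_event``, otherwise ``true_event``.

By default the ``suicid*`` token must precede the ``ideat*`` token
(``require_order=True``) but need not be adjacent, so "suicidal thoughts and
ideation" still matches while "ideation, possibly suicidal" does not.  Both
switches and all three gazetteers are user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_model import (
    DEFAULT_CONTEXT_BUDGET,
    NON_TRUE_EVENT,
    TRUE_EVENT,
    ClinicalDocument,
    ConceptMention,
    Gazetteer,
    GazetteerEntry,
    MentionClassification,
    ValidationError,
    build_context_string,
)
from .preprocess import (
    PreprocessedDocument,
    load_data_text,
    match_gazetteer,
    preprocess_document,
)

__all__ = [
    "IdeationRuleConfig",
    "default_ideation_config",
    "detect_ideation",
    "classify_ideation",
    "run_ideation",
]


def _gazetteer_from_text(text: str, name: str) -> Gazetteer:
    entries = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            entries.append(GazetteerEntry(tuple(stripped.split()), stripped))
    return Gazetteer(name=name, entries=entries)


@dataclass
class IdeationRuleConfig:
    """Configuration of the ideation rules.

    ``positive_pattern`` holds one entry of exactly two (usually wildcard)
    tokens that must co-occur in a sentence; the two negation gazetteers are
    the sentence-scope and phrase-scope veto lists.
    """

    positive_pattern: Gazetteer
    negation_sentence: Gazetteer
    negation_phrase: Gazetteer
    require_order: bool = True
    require_adjacency: bool = False
    context_budget: int = DEFAULT_CONTEXT_BUDGET

    def __post_init__(self) -> None:
        if not self.positive_pattern.entries:
            raise ValidationError("positive pattern gazetteer is empty")
        for entry in self.positive_pattern.entries:
            if len(entry.tokens) != 2:
                raise ValidationError(
                    "positive pattern entries must have exactly two tokens"
                )


def default_ideation_config(**overrides) -> IdeationRuleConfig:
    """The packaged configuration: suicid* + ideat*, two default gazetteers."""
    cfg = IdeationRuleConfig(
        positive_pattern=Gazetteer(
            name="ideation_positive",
            entries=[GazetteerEntry(("suicid*", "ideat*"), "suicid* ideat*")],
        ),
        negation_sentence=_gazetteer_from_text(
            load_data_text("ideation_negation_sentence.txt"), "negation_sentence"
        ),
        negation_phrase=_gazetteer_from_text(
            load_data_text("ideation_negation_phrase.txt"), "negation_phrase"
        ),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _wild_match(pattern_tok: str, surface: str) -> bool:
    surface = surface.lower()
    pattern_tok = pattern_tok.lower()
    if pattern_tok.endswith("*"):
        return surface.startswith(pattern_tok[:-1])
    return surface == pattern_tok


def detect_ideation(
    doc: ClinicalDocument | PreprocessedDocument,
    config: IdeationRuleConfig | None = None,
) -> list[ConceptMention]:
    """One ideation mention per sentence where both pattern tokens co-occur.

    The mention's match is the minimal token span covering the closest
    qualifying token pair; the context excerpt is built from surrounding
    sentences under the configured budget.
    """
    if config is None:
        config = default_ideation_config()
    pre = doc if isinstance(doc, PreprocessedDocument) else preprocess_document(doc)
    document = pre.document
    mentions: list[ConceptMention] = []
    first_tok, second_tok = config.positive_pattern.entries[0].tokens
    for sentence, tokens in zip(pre.sentences, pre.tokens):
        firsts = [i for i, t in enumerate(tokens) if _wild_match(first_tok, t.surface)]
        seconds = [i for i, t in enumerate(tokens) if _wild_match(second_tok, t.surface)]
        if not firsts or not seconds:
            continue
        pairs = []
        for i in firsts:
            for j in seconds:
                if i == j:
                    continue
                if config.require_order and j < i:
                    continue
                if config.require_adjacency and abs(j - i) != 1:
                    continue
                pairs.append((abs(j - i), min(i, j), i, j))
        if not pairs:
            continue
        _, _, i, j = min(pairs)
        lo, hi = min(i, j), max(i, j)
        start, end = tokens[lo].start, tokens[hi].end
        mentions.append(
            ConceptMention(
                doc_id=document.doc_id,
                patient_id=document.patient_id,
                concept="ideation",
                sentence_index=sentence.index,
                match=document.text[start:end],
                match_start=start,
                match_end=end,
                context_string=build_context_string(
                    document.text,
                    pre.sentences,
                    sentence.index,
                    start,
                    end,
                    config.context_budget,
                ),
            )
        )
    return mentions


def classify_ideation(
    mention: ConceptMention,
    pre: PreprocessedDocument,
    config: IdeationRuleConfig | None = None,
) -> MentionClassification:
    """Label a detected mention: negation-gazetteer hit in sentence => veto."""
    if config is None:
        config = default_ideation_config()
    tokens = pre.sentence_tokens(mention.sentence_index)
    negated = bool(
        match_gazetteer(config.negation_sentence, tokens)
        or match_gazetteer(config.negation_phrase, tokens)
    )
    label = NON_TRUE_EVENT if negated else TRUE_EVENT
    return MentionClassification(key=mention.key, label=label, confidence=1.0)


def run_ideation(corpus, config: IdeationRuleConfig | None = None):
    """Detect + classify over a whole corpus; returns (mentions, classifications)."""
    if config is None:
        config = default_ideation_config()
    mentions: list[ConceptMention] = []
    classifications: list[MentionClassification] = []
    for doc in corpus:
        pre = preprocess_document(doc)
        for mention in detect_ideation(pre, config):
            mentions.append(mention)
            classifications.append(classify_ideation(mention, pre, config))
    return mentions, classifications
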