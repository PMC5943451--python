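"""ConText-style assertion flags for concept mentions.

A trigger lexicon marks tokens that open an assertion scope: *pre* triggers
("no", "denied", "history of", "mother", ...) project forward over the
following tokens; *post* triggers ("was ruled out") project backward.  A
scope closes at the sentence end, at a termination trigger ("but",
"however"), or after ``max_scope`` tokens, whichever comes first.  A mention
falling inside an active scope gets the corresponding flag:

* ``negated`` — negation_pre / negation_post triggers;
* ``historical`` — temporal irrelevance; historical *and* hypothetical
  triggers both set it (three output flags, four trigger families);
* ``experiencer_other`` — the concept refers to someone other than the
  patient (family members, friends...).

Default scopes follow the published ConText conventions: a short window
(5 tokens) for negation, the whole sentence for historical/experiencer.
Scopes never cross sentence boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .corpus_model import ValidationError
from .preprocess import load_data_text

__all__ = [
    "CATEGORY_FLAGS",
    "ContextFlags",
    "Trigger",
    "TriggerLexicon",
    "default_trigger_lexicon",
    "apply_context",
]

TRIGGER_CATEGORIES = (
    "negation_pre",
    "negation_post",
    "historical",
    "hypothetical",
    "experiencer",
    "termination",
)

#: trigger category -> ContextFlags attribute it activates
CATEGORY_FLAGS = {
    "negation_pre": "negated",
    "negation_post": "negated",
    "historical": "historical",
    "hypothetical": "historical",
    "experiencer": "experiencer_other",
}

#: sentinel max_scope meaning "to the sentence boundary"
WHOLE_SENTENCE = 999


@dataclass
class ContextFlags:
    """Assertion status of one mention, with the triggers responsible."""

    negated: bool = False
    historical: bool = False
    experiencer_other: bool = False
    triggering_terms: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class Trigger:
    """One lexicon entry: token pattern (wildcards allowed), category, scope."""

    tokens: tuple[str, ...]
    category: str
    max_scope: int

    def __post_init__(self) -> None:
        if self.category not in TRIGGER_CATEGORIES:
            raise ValidationError(f"unknown trigger category {self.category!r}")
        if self.max_scope < 1:
            raise ValidationError("max_scope must be >= 1")
        if not self.tokens:
            raise ValidationError("empty trigger pattern")

    @property
    def surface(self) -> str:
        return " ".join(self.tokens)


@dataclass
class TriggerLexicon:
    triggers: list[Trigger] = field(default_factory=list)

    @classmethod
    def from_text(cls, text: str) -> "TriggerLexicon":
        triggers = []
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"trigger line {lineno}: expected pattern<TAB>category<TAB>max_scope"
                )
            pattern, category, scope = parts
            triggers.append(
                Trigger(tuple(pattern.split()), category.strip(), int(scope))
            )
        return cls(triggers=triggers)

    @classmethod
    def from_file(cls, path) -> "TriggerLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read())


def default_trigger_lexicon() -> TriggerLexicon:
    return TriggerLexicon.from_text(load_data_text("context_triggers.tsv"))


def _tok_match(pattern_tok: str, surface: str) -> bool:
    surface = surface.lower()
    pattern_tok = pattern_tok.lower()
    if pattern_tok.endswith("*"):
        return surface.startswith(pattern_tok[:-1])
    return surface == pattern_tok


def _find_occurrences(tokens: Sequence, trigger: Trigger) -> list[tuple[int, int]]:
    hits = []
    n = len(trigger.tokens)
    for i in range(len(tokens) - n + 1):
        if all(_tok_match(trigger.tokens[j], tokens[i + j].surface) for j in range(n)):
            hits.append((i, i + n))
    return hits


def apply_context(
    mention_token_range: tuple[int, int],
    sentence_tokens: Sequence,
    lexicon: TriggerLexicon | None = None,
) -> ContextFlags:
    """Compute assertion flags for a mention within its sentence.

    ``mention_token_range`` is the half-open token-index range of the mention
    inside ``sentence_tokens``.  Scopes are confined to the sentence.
    """
    if lexicon is None:
        lexicon = default_trigger_lexicon()
    m_start, m_end = mention_token_range
    n = len(sentence_tokens)

    termination_starts = sorted(
        start
        for trig in lexicon.triggers
        if trig.category == "termination"
        for (start, _end) in _find_occurrences(sentence_tokens, trig)
    )

    flags = ContextFlags()
    for trig in lexicon.triggers:
        if trig.category == "termination":
            continue
        flag_attr = CATEGORY_FLAGS[trig.category]
        for t_start, t_end in _find_occurrences(sentence_tokens, trig):
            if t_start < m_end and m_start < t_end:
                continue  # the trigger overlaps the mention itself
            if trig.category == "negation_post":
                scope_end = t_start
                scope_start = max(0, t_start - trig.max_scope)
                for term in reversed(termination_starts):
                    if scope_start <= term < scope_end:
                        scope_start = term + 1
                        break
            else:
                scope_start = t_end
                scope_end = min(n, t_end + trig.max_scope)
                for term in termination_starts:
                    if scope_start <= term < scope_end:
                        scope_end = term
                        break
            if scope_start < m_end and m_start < scope_end:
                flags.triggering_terms.append((trig.surface, trig.category))
                setattr(flags, flag_attr, True)
    return flags
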