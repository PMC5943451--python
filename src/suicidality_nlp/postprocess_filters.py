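"""Rule-based post-processing of machine-labelled attempt positives.

Classifiers trained on narrative text over-call neutral occurrences of
attempt terms: questionnaire items ("Have you ever attempted suicide?"),
bare subheadings ("Past suicide attempts", "b) Suicide attempts x"),
ambiguous fragments and negated statements.  This layer re-examines the two
output fields of every positive classification — the ``match`` text and the
``context_string`` excerpt — against a rulebook of case-insensitive regular
expressions, and vetoes (relabels ``non_true_event``) any positive whose
mention matches a rule.  Non-positives are never touched, so recall can only
decrease while title/negation false positives are removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_model import (
    NON_TRUE_EVENT,
    TRUE_EVENT,
    ConceptMention,
    ConsistencyError,
    MentionClassification,
    ValidationError,
)
from .preprocess import load_data_text

__all__ = [
    "RULE_CATEGORIES",
    "ExclusionRule",
    "ExclusionRulebook",
    "default_rulebook",
    "apply_filters",
]

RULE_CATEGORIES = ("title_neutral", "ambiguous", "negation_before_match")
RULE_FIELDS = ("match", "context_string")


@dataclass(frozen=True)
class ExclusionRule:
    """One veto rule: regex over a mention field, with a reason category."""

    rule_id: str
    target_field: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if self.target_field not in RULE_FIELDS:
            raise ValidationError(
                f"rule {self.rule_id!r}: field must be one of {RULE_FIELDS}"
            )
        if self.category not in RULE_CATEGORIES:
            raise ValidationError(
                f"rule {self.rule_id!r}: category must be one of {RULE_CATEGORIES}"
            )
        try:
            compiled = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValidationError(
                f"rule {self.rule_id!r}: pattern does not compile ({exc})"
            ) from exc
        object.__setattr__(self, "_compiled", compiled)

    def matches(self, mention: ConceptMention) -> bool:
        value = getattr(mention, self.target_field)
        return self._compiled.search(value) is not None


@dataclass
class ExclusionRulebook:
    rules: list[ExclusionRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValidationError("rule_ids must be unique")

    def matching_rules(self, mention: ConceptMention) -> list[ExclusionRule]:
        return [rule for rule in self.rules if rule.matches(mention)]

    @classmethod
    def from_text(cls, text: str) -> "ExclusionRulebook":
        rules = []
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValidationError(
                    f"rulebook line {lineno}: expected rule_id<TAB>field<TAB>pattern<TAB>category"
                )
            rules.append(ExclusionRule(*[p.strip() if i != 2 else p for i, p in enumerate(parts)]))
        return cls(rules=rules)

    @classmethod
    def from_file(cls, path) -> "ExclusionRulebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read())


def default_rulebook() -> ExclusionRulebook:
    """The packaged rulebook: heading/questionnaire/ambiguous/negation vetoes."""
    return ExclusionRulebook.from_text(load_data_text("exclusion_rules.tsv"))


def apply_filters(
    classifications: Sequence[MentionClassification],
    mentions: Sequence[ConceptMention] | Mapping[tuple, ConceptMention],
    rulebook: ExclusionRulebook | None = None,
):
    """Veto positive classifications whose mention matches any rule.

    Returns ``(filtered_classifications, exclusion_log)`` where the log is a
    list of ``(mention_key, rule_id)`` pairs, one per matching rule.  The
    operation is idempotent and only ever flips ``true_event`` to
    ``non_true_event``.
    """
    if rulebook is None:
        rulebook = default_rulebook()
    if isinstance(mentions, Mapping):
        by_key = dict(mentions)
    else:
        by_key = {m.key: m for m in mentions}
    missing = [c.key for c in classifications if c.key not in by_key]
    if missing:
        raise ConsistencyError(f"classifications without a mention: {missing[:5]}")
    filtered: list[MentionClassification] = []
    log: list[tuple[tuple, str]] = []
    for cls in classifications:
        if cls.label != TRUE_EVENT:
            filtered.append(cls)
            continue
        hits = rulebook.matching_rules(by_key[cls.key])
        if hits:
            for rule in hits:
                log.append((cls.key, rule.rule_id))
            filtered.append(cls.relabelled(NON_TRUE_EVENT))
        else:
            filtered.append(cls)
    return filtered, log
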