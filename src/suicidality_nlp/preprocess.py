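"""Text preprocessing: sentences, tokens, stems, POS tags, gazetteer matching.

Clinical notes arrive in any layout — narrative prose, questionnaire items,
bare subheadings like ``Past suicide attempts`` — so the sentence splitter is
deliberately rule-based: it breaks after sentence-final punctuation followed
by whitespace and at every newline, which makes heading lines their own
sentences (the neutral-mention filters depend on that).

Stemming is classic Porter suffix stripping and the POS tagger is a small
deterministic lexicon + suffix tagger over Penn-style tags; downstream
consumers only require determinism and one tag per token, since tags are used
as opaque feature strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .corpus_model import (
    ClinicalDocument,
    Gazetteer,
    GazetteerEntry,
    Sentence,
    Token,
)

__all__ = [
    "split_sentences",
    "tokenize",
    "PorterStemmer",
    "stem",
    "pos_tag",
    "StopWordList",
    "default_stopwords",
    "GazetteerMatch",
    "match_gazetteer",
    "PreprocessedDocument",
    "preprocess_document",
    "load_data_text",
]


def load_data_text(filename: str) -> str:
    """Read a packaged data file (lexicons, trigger lists, rulebook)."""
    return (resources.files("suicidality_nlp") / "data" / filename).read_text(
        encoding="utf-8"
    )


def data_path(filename: str):
    return resources.files("suicidality_nlp") / "data" / filename


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# End-of-sentence punctuation (optionally followed by closing quotes/brackets)
# before whitespace.  Newline runs are unconditional boundaries.
_EOS = re.compile(r"[.!?;]+[\"'’)\]]*(?=\s)|\n")


def split_sentences(doc: ClinicalDocument) -> list[Sentence]:
    """Split a document into ordered, non-overlapping sentences.

    Boundaries: after ``[.!?;]`` runs followed by whitespace, and at every
    newline (a line without terminal punctuation is still a sentence).
    Whitespace-only segments are dropped; each sentence's span slices the
    original text to exactly its surface.
    """
    text = doc.text
    boundaries: list[int] = []
    for m in _EOS.finditer(text):
        boundaries.append(m.end())
    boundaries.append(len(text))
    sentences: list[Sentence] = []
    prev = 0
    for cut in boundaries:
        if cut <= prev:
            continue
        segment = text[prev:cut]
        stripped = segment.strip()
        if stripped:
            start = prev + (len(segment) - len(segment.lstrip()))
            end = start + len(stripped)
            sentences.append(
                Sentence(
                    doc_id=doc.doc_id,
                    index=len(sentences),
                    start=start,
                    end=end,
                    text=text[start:end],
                )
            )
        prev = cut
    return sentences


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Alphanumeric runs (internal apostrophes kept so "didn't" is one token),
# plus every other non-space character as a standalone token.
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:['’][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")


def tokenize(sentence: Sentence) -> list[Token]:
    """Tokenize a sentence; offsets are document-level and exact."""
    tokens: list[Token] = []
    for m in _TOKEN.finditer(sentence.text):
        tokens.append(
            Token(
                sentence_index=sentence.index,
                start=sentence.start + m.start(),
                end=sentence.start + m.end(),
                surface=m.group(),
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

class PorterStemmer:
    """The classic Porter (1980) suffix-stripping stemmer, case-folding.

    Implemented from the published algorithm definition (steps 1a-5b with the
    m-measure over the [C](VC)^m[V] form of a word).
    """

    _VOWELS = "aeiou"

    def _is_cons(self, word: str, i: int) -> bool:
        ch = word[i]
        if ch in self._VOWELS:
            return False
        if ch == "y":
            return i == 0 or not self._is_cons(word, i - 1)
        return True

    def _measure(self, stem_part: str) -> int:
        # Number of VC sequences in the [C](VC)^m[V] decomposition.
        m = 0
        prev_vowel = False
        for i in range(len(stem_part)):
            cons = self._is_cons(stem_part, i)
            if cons and prev_vowel:
                m += 1
            prev_vowel = not cons
        return m

    def _has_vowel(self, stem_part: str) -> bool:
        return any(not self._is_cons(stem_part, i) for i in range(len(stem_part)))

    def _ends_double_cons(self, word: str) -> bool:
        return (
            len(word) >= 2
            and word[-1] == word[-2]
            and self._is_cons(word, len(word) - 1)
        )

    def _ends_cvc(self, word: str) -> bool:
        # *o: stem ends cvc where the final consonant is not w, x or y.
        if len(word) < 3:
            return False
        return (
            self._is_cons(word, len(word) - 3)
            and not self._is_cons(word, len(word) - 2)
            and self._is_cons(word, len(word) - 1)
            and word[-1] not in "wxy"
        )

    def _replace(self, word: str, suffix: str, repl: str, min_m: int) -> str | None:
        if not word.endswith(suffix):
            return None
        stem_part = word[: len(word) - len(suffix)]
        if self._measure(stem_part) > min_m - 1:
            return stem_part + repl
        return word  # suffix present but condition failed: rule consumed

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ]
    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]
    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]

    def stem(self, surface: str) -> str:
        word = surface.lower()
        if len(word) <= 2:
            return word
        # Step 1a
        if word.endswith("sses"):
            word = word[:-2]
        elif word.endswith("ies"):
            word = word[:-2]
        elif word.endswith("ss"):
            pass
        elif word.endswith("s"):
            word = word[:-1]
        # Step 1b
        if word.endswith("eed"):
            if self._measure(word[:-3]) > 0:
                word = word[:-1]
        else:
            flag = False
            if word.endswith("ed") and self._has_vowel(word[:-2]):
                word, flag = word[:-2], True
            elif word.endswith("ing") and self._has_vowel(word[:-3]):
                word, flag = word[:-3], True
            if flag:
                if word.endswith(("at", "bl", "iz")):
                    word += "e"
                elif self._ends_double_cons(word) and word[-1] not in "lsz":
                    word = word[:-1]
                elif self._measure(word) == 1 and self._ends_cvc(word):
                    word += "e"
        # Step 1c
        if word.endswith("y") and self._has_vowel(word[:-1]):
            word = word[:-1] + "i"
        # Step 2: longest matching suffix wins
        best = None
        for suffix, repl in self._STEP2:
            if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
                best = (suffix, repl)
        if best is not None:
            word = self._replace(word, best[0], best[1], 1) or word
        # Step 3
        best = None
        for suffix, repl in self._STEP3:
            if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
                best = (suffix, repl)
        if best is not None:
            word = self._replace(word, best[0], best[1], 1) or word
        # Step 4
        best4 = None
        for suffix in self._STEP4:
            if word.endswith(suffix) and (best4 is None or len(suffix) > len(best4)):
                best4 = suffix
        if best4 is not None:
            stem_part = word[: len(word) - len(best4)]
            if self._measure(stem_part) > 1:
                if best4 == "ion":
                    if stem_part.endswith(("s", "t")):
                        word = stem_part
                else:
                    word = stem_part
        # Step 5a
        if word.endswith("e"):
            m = self._measure(word[:-1])
            if m > 1 or (m == 1 and not self._ends_cvc(word[:-1])):
                word = word[:-1]
        # Step 5b
        if self._measure(word) > 1 and self._ends_double_cons(word) and word.endswith("l"):
            word = word[:-1]
        return word


_STEMMER = PorterStemmer()


def stem(surface: str) -> str:
    """Stem one token surface (case-folded Porter stem)."""
    if not surface:
        raise ValueError("cannot stem an empty surface")
    return _STEMMER.stem(surface)


# ---------------------------------------------------------------------------
# POS tagging
# ---------------------------------------------------------------------------

_TAG_LEXICON = {
    # pronouns
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "him": "PRP", "them": "PRP", "himself": "PRP",
    "herself": "PRP", "themselves": "PRP", "myself": "PRP",
    "her": "PRP$", "his": "PRP$", "their": "PRP$", "my": "PRP$", "your": "PRP$",
    "its": "PRP$", "our": "PRP$",
    # determiners
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "any": "DT", "some": "DT", "each": "DT",
    "no": "DT", "all": "DT", "both": "DT",
    # auxiliaries / common verbs
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG",
    "do": "VBP", "does": "VBZ", "did": "VBD", "done": "VBN",
    "says": "VBZ", "said": "VBD", "made": "VBD", "took": "VBD", "taken": "VBN",
    "went": "VBD", "felt": "VBD", "gave": "VBD", "got": "VBD", "saw": "VBD",
    # modals
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "shall": "MD",
    "should": "MD", "may": "MD", "might": "MD", "must": "MD", "cannot": "MD",
    # adverbs / negation
    "not": "RB", "never": "RB", "n't": "RB", "very": "RB", "also": "RB",
    "now": "RB", "ever": "RB", "again": "RB", "here": "RB", "there": "EX",
    "when": "WRB", "where": "WRB", "how": "WRB", "why": "WRB",
    "who": "WP", "what": "WP", "which": "WDT",
    # prepositions / subordinators
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "without": "IN", "from": "IN", "into": "IN", "about": "IN",
    "after": "IN", "before": "IN", "over": "IN", "under": "IN", "during": "IN",
    "since": "IN", "while": "IN", "against": "IN", "as": "IN", "if": "IN",
    "because": "IN", "although": "IN", "though": "IN", "whether": "IN",
    "to": "TO",
    # conjunctions
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "so": "CC", "yet": "CC",
}

_PUNCT_TAGS = {
    ".": ".", "!": ".", "?": ".", ",": ",", ";": ":", ":": ":",
    "(": "(", ")": ")", "“": "``", "”": "''", '"': "''", "'": "''",
    "-": ":", "–": ":", "—": ":", "/": ":",
}

_NUM = re.compile(r"^\d+(?:\.\d+)?$")


def _tag_one(surface: str) -> str:
    low = surface.lower()
    if low in _TAG_LEXICON:
        return _TAG_LEXICON[low]
    if _NUM.match(surface):
        return "CD"
    if not any(ch.isalnum() for ch in surface):
        return _PUNCT_TAGS.get(surface, "SYM")
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    if low.endswith("ly") and len(low) > 3:
        return "RB"
    if low.endswith(("ous", "ful", "ive", "able", "ible", "al", "ic")) and len(low) > 4:
        return "JJ"
    if low.endswith("es") and len(low) > 3 and not low.endswith("ss"):
        return "VBZ" if low.endswith(("ies", "ches", "shes")) else "NNS"
    if low.endswith("s") and len(low) > 3 and not low.endswith("ss"):
        return "NNS"
    return "NN"


def pos_tag(tokens: Sequence[Token]) -> list[Token]:
    """Assign one deterministic Penn-style tag (and stem) to every token."""
    tagged: list[Token] = []
    for tok in tokens:
        tagged.append(
            Token(
                sentence_index=tok.sentence_index,
                start=tok.start,
                end=tok.end,
                surface=tok.surface,
                stem=_STEMMER.stem(tok.surface),
                pos=_tag_one(tok.surface),
            )
        )
    return tagged


# ---------------------------------------------------------------------------
# Stop words
# ---------------------------------------------------------------------------

@dataclass
class StopWordList:
    """Lowercased stop tokens, loaded from a plain-text one-per-line file."""

    terms: frozenset[str]

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self.terms

    @classmethod
    def from_text(cls, text: str) -> "StopWordList":
        terms = frozenset(
            line.strip().lower()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )
        return cls(terms=terms)

    @classmethod
    def from_file(cls, path) -> "StopWordList":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read())


def default_stopwords() -> StopWordList:
    """The packaged English stop list (negation cues deliberately excluded)."""
    return StopWordList.from_text(load_data_text("stopwords_en.txt"))


# ---------------------------------------------------------------------------
# Gazetteer matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazetteerMatch:
    """One gazetteer pattern hit over a contiguous token run."""

    entry: GazetteerEntry
    token_start: int  # index into the sentence token list
    token_end: int  # exclusive
    start: int  # document character offsets
    end: int

    def matched_text(self, text: str) -> str:
        return text[self.start : self.end]


def _token_matches(pattern_tok: str, surface: str, fold: bool) -> bool:
    if fold:
        pattern_tok = pattern_tok.lower()
        surface = surface.lower()
    if pattern_tok.endswith("*"):
        return surface.startswith(pattern_tok[:-1])
    return surface == pattern_tok


def match_gazetteer(
    gazetteer: Gazetteer, tokens: Sequence[Token]
) -> list[GazetteerMatch]:
    """Find every gazetteer pattern over the sentence's token sequence.

    A pattern matches a contiguous token run where each literal pattern token
    equals the text token (under the gazetteer's case policy) and each
    wildcard token is a prefix of it.  Overlapping matches of different
    patterns are all reported; duplicate (pattern, span) hits are not.
    """
    fold = gazetteer.case_policy == "fold"
    matches: list[GazetteerMatch] = []
    seen: set[tuple[tuple[str, ...], int]] = set()
    for start_idx in range(len(tokens)):
        for entry in gazetteer.entries:
            n = len(entry.tokens)
            if start_idx + n > len(tokens):
                continue
            if (entry.tokens, start_idx) in seen:
                continue
            if all(
                _token_matches(entry.tokens[j], tokens[start_idx + j].surface, fold)
                for j in range(n)
            ):
                seen.add((entry.tokens, start_idx))
                matches.append(
                    GazetteerMatch(
                        entry=entry,
                        token_start=start_idx,
                        token_end=start_idx + n,
                        start=tokens[start_idx].start,
                        end=tokens[start_idx + n - 1].end,
                    )
                )
    return matches


# ---------------------------------------------------------------------------
# Whole-document preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedDocument:
    """A document with its sentences and per-sentence tagged tokens."""

    document: ClinicalDocument
    sentences: list[Sentence] = field(default_factory=list)
    tokens: list[list[Token]] = field(default_factory=list)  # per sentence

    def sentence_tokens(self, index: int) -> list[Token]:
        return self.tokens[index]


def preprocess_document(doc: ClinicalDocument) -> PreprocessedDocument:
    """Split, tokenize, stem and tag a document in one pass."""
    sentences = split_sentences(doc)
    tokens = [pos_tag(tokenize(s)) for s in sentences]
    return PreprocessedDocument(document=doc, sentences=sentences, tokens=tokens)
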