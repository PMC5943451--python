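"""Independent brute-force oracles shared by property and acceptance tests.

These deliberately re-derive results through a different code path than the
library (explicit interval walks, regex re-matching) so that agreement is a
real check, not a tautology.
"""

from suicidality_nlp.context_modifiers import CATEGORY_FLAGS, ContextFlags
from suicidality_nlp.corpus_model import Token


def make_tokens(words, sentence_index=0):
    """Build a token list from plain words (offsets synthesised)."""
    toks = []
    pos = 0
    for w in words:
        toks.append(
            Token(sentence_index=sentence_index, start=pos, end=pos + len(w), surface=w)
        )
        pos += len(w) + 1
    return toks


def _surface_match(pattern_tok, word):
    word = word.lower()
    pattern_tok = pattern_tok.lower()
    if pattern_tok.endswith("*"):
        return word.startswith(pattern_tok[:-1])
    return word == pattern_tok


def _occurrences(words, trigger):
    pat = trigger.tokens
    return [
        (i, i + len(pat))
        for i in range(len(words) - len(pat) + 1)
        if all(_surface_match(pat[j], words[i + j]) for j in range(len(pat)))
    ]


def context_flags_bruteforce(mention_range, words, lexicon):
    """Explicit token-walk scope computation (the oracle for apply_context)."""
    m_start, m_end = mention_range
    n = len(words)
    term_starts = {
        s
        for trig in lexicon.triggers
        if trig.category == "termination"
        for (s, _e) in _occurrences(words, trig)
    }
    flags = ContextFlags()
    for trig in lexicon.triggers:
        if trig.category == "termination":
            continue
        for t_start, t_end in _occurrences(words, trig):
            if t_start < m_end and m_start < t_end:
                continue
            scope = set()
            if trig.category == "negation_post":
                p = t_start - 1
                while p >= 0 and p >= t_start - trig.max_scope:
                    if p in term_starts:
                        break
                    scope.add(p)
                    p -= 1
            else:
                p = t_end
                while p < n and p < t_end + trig.max_scope:
                    if p in term_starts:
                        break
                    scope.add(p)
                    p += 1
            if scope & set(range(m_start, m_end)):
                setattr(flags, CATEGORY_FLAGS[trig.category], True)
                flags.triggering_terms.append((trig.surface, trig.category))
    return flags
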