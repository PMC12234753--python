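"""Small rule-based English lemmatizer and edit-distance-1 spell repair.

The free descriptions are single English words (one per response box), so a
compact suffix-rule lemmatizer with an exception table covers the
inflectional and the common derivational patterns seen in trait vocabulary
(plurals, -ing/-ed forms, comparatives, -ity/-ness nominalizations, -ly
adverbs).  When a lexicon is supplied, a candidate reduction is accepted
only if the lexicon contains it, which keeps the rules from overfiring.
"""

from __future__ import annotations

from typing import Iterable, Optional

_EXCEPTIONS = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "teeth": "tooth",
    "feet": "foot",
    "better": "good",
    "best": "good",
    "worse": "bad",
    "worst": "bad",
}

_VOWELS = set("aeiou")

# (suffix, replacement) tried in order; longest/most specific first.
_RULES = [
    ("ivity", "ive"),     # creativity -> creative
    ("inity", "ine"),     # femininity -> feminine
    ("iness", "y"),       # happiness -> happy
    ("ness", ""),         # kindness -> kind
    ("ility", "le"),      # sociability -> sociable
    ("ies", "y"),         # worries -> worry
    ("ied", "y"),         # worried -> worry
    ("ily", "y"),         # happily -> happy
    ("iest", "y"),        # happiest -> happy
    ("ier", "y"),         # happier -> happy
    ("ing", ""),          # talking -> talk
    ("ing", "e"),         # smiling -> smile
    ("ed", ""),           # talked -> talk
    ("ed", "e"),          # bored -> bore
    ("ity", "e"),         # masculinity handled above; generic -ity -> -e
    ("ity", ""),
    ("ly", ""),           # quickly -> quick
    ("es", ""),           # watches -> watch
    ("s", ""),            # words -> word
]


def _candidates(word: str) -> Iterable[str]:
    for suf, rep in _RULES:
        if word.endswith(suf) and len(word) > len(suf) + 2:
            stem = word[: -len(suf)] + rep
            yield stem
            # undouble a trailing doubled consonant (running -> run)
            if (
                len(stem) >= 3
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "sl"
            ):
                yield stem[:-1]


def lemmatize(word: str, lexicon: Optional[frozenset] = None) -> str:
    """Reduce ``word`` to a base form.

    With a lexicon, the first rule candidate present in the lexicon wins;
    a word already in the lexicon is returned unchanged.  Without a
    lexicon, the first rule that applies wins, and words no rule matches
    are returned unchanged.
    """
    w = word.strip().lower()
    if w in _EXCEPTIONS:
        return _EXCEPTIONS[w]
    if lexicon is not None:
        if w in lexicon:
            return w
        for cand in _candidates(w):
            if cand in lexicon:
                return cand
        return w
    for cand in _candidates(w):
        return cand
    return w


def within_edit_one(a: str, b: str) -> bool:
    """True if Levenshtein distance between a and b is at most 1."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: try deleting each position's first mismatch
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def spell_correct(word: str, lexicon: frozenset) -> Optional[str]:
    """Return the unique-ish lexicon word within edit distance 1, if any.

    Ties are broken deterministically by (length difference, alphabetical
    order).  Returns None when no lexicon word is within distance 1.
    """
    if word in lexicon:
        return word
    matches = sorted(
        (abs(len(c) - len(word)), c)
        for c in lexicon
        if abs(len(c) - len(word)) <= 1 and within_edit_one(word, c)
    )
    return matches[0][1] if matches else None
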