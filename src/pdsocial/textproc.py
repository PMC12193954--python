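"""Low-level text utilities shared across the pipeline.

Tokenization, the bundled stop-word list, a classic Porter suffix-stripping
stemmer (used for dictionary matching, e.g. "trembling" -> "trembl"), and a
rule-based English noun lemmatizer (used for model features, where gerunds
such as "trembling" are deliberately left unchanged because the default part
of speech is noun).
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

__all__ = [
    "tokenize",
    "strip_punctuation",
    "stopwords",
    "remove_stopwords",
    "porter_stem",
    "lemmatize_noun",
]

_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def strip_punctuation(text: str) -> str:
    """Remove punctuation and symbol characters ("Parkinson's" -> "Parkinsons")."""
    return _PUNCT_RE.sub("", text)


def collapse_whitespace(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return strip_punctuation(text.lower()).split()


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    """The fixed English stop-word list bundled with the package."""
    raw = resources.files("pdsocial.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w for w in raw.split() if w and not w.startswith("#"))


def remove_stopwords(tokens: list[str]) -> list[str]:
    sw = stopwords()
    return [t for t in tokens if t not in sw]


# ---------------------------------------------------------------------------
# Porter stemmer (original 1980 algorithm)
# ---------------------------------------------------------------------------


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in "aeiou":
        return False
    if ch == "y":
        return True if i == 0 else not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions (the 'm' of the algorithm)."""
    n = 0
    i = 0
    length = len(stem)
    while i < length and _is_cons(stem, i):
        i += 1
    while i < length:
        while i < length and not _is_cons(stem, i):
            i += 1
        if i >= length:
            break
        while i < length and _is_cons(stem, i):
            i += 1
        n += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return len(word) >= 2 and word[-1] == word[-2] and _is_cons(word, len(word) - 1)


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (_is_cons(word, -3 + len(word)) and not _is_cons(word, -2 + len(word)) and _is_cons(word, -1 + len(word))):
        return False
    return word[-1] not in "wxy"


def _replace_suffix(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + repl
    return word


@lru_cache(maxsize=65536)
def porter_stem(word: str) -> str:
    """Stem a single lowercase token with the classic Porter algorithm."""
    w = word
    if len(w) <= 2:
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    flag = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed"):
        if _has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
    elif w.endswith("ing"):
        if _has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ):
        out = _replace_suffix(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # Step 3
    for suffix, repl in (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ):
        out = _replace_suffix(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # Step 4
    for suffix in (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ):
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                continue
            if _measure(stem) > 1:
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Noun-default lemmatizer
# ---------------------------------------------------------------------------

_IRREGULAR_NOUNS = {
    "feet": "foot", "teeth": "tooth", "geese": "goose", "mice": "mouse",
    "lice": "louse", "men": "man", "women": "woman", "children": "child",
    "people": "person", "oxen": "ox", "knives": "knife", "wives": "wife",
    "lives": "life", "leaves": "leaf", "halves": "half", "selves": "self",
    "shelves": "shelf", "loaves": "loaf", "wolves": "wolf", "calves": "calf",
    "scarves": "scarf", "thieves": "thief",
}

# Words ending in s that are not inflected plurals.
_UNINFLECTED = {
    "news", "series", "species", "physics", "mathematics", "diabetes",
    "arthritis", "analysis", "diagnosis", "dyskinesias", "always", "perhaps",
    "class", "glass", "grass", "kindness", "illness", "fitness",
}


def lemmatize_noun(token: str) -> str:
    """Reduce an English noun to singular form; other words pass through.

    The default part of speech is noun, so verb inflections like gerunds are
    intentionally not reduced ("trembling" stays "trembling").
    """
    if token in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[token]
    if token in _UNINFLECTED or len(token) <= 3:
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "ches", "shes", "xes", "zes")):
        return token[:-2]
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith("s"):
        return token[:-1]
    return token
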