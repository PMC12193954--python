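"""PD term dictionary: loading, text preprocessing, and post flagging.

The dictionary is deliberately over-inclusive — ambiguous terms such as
"fell" or "tired" are included so that candidate posts are not missed; a
downstream classifier separates genuinely PD-related posts from incidental
matches.  Matching is performed on preprocessed tokens (lowercase, no
punctuation, stop words removed) both unstemmed and Porter-stemmed, with
multi-word terms matched as consecutive token sequences.  Explicit-mention
rules ("parkinson" substring, standalone "PD" word) are applied to the raw
text and override everything downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .textproc import porter_stem, remove_stopwords, tokenize

log = logging.getLogger(__name__)

__all__ = [
    "TermDictionary",
    "load_dictionary",
    "preprocess_for_match",
    "dictionary_flag",
    "explicit_mention",
]

TAGS = {"exercise", "medication", "symptom", "advocacy", "other"}

# Case-sensitive standalone "PD", so that e.g. "updated" never matches.
_PD_ABBREV_RE = re.compile(r"\bPD\b")


@dataclass
class TermDictionary:
    """A set of lowercase terms with stems and optional tags."""

    tags: dict[str, str | None]
    #: term -> preprocessed unstemmed token sequence
    unstemmed: dict[str, tuple[str, ...]] = field(repr=False, default_factory=dict)
    #: term -> preprocessed stemmed token sequence
    stemmed: dict[str, tuple[str, ...]] = field(repr=False, default_factory=dict)
    _indexes: tuple = field(repr=False, default=())

    @property
    def terms(self) -> set[str]:
        return set(self.tags)

    @property
    def stems(self) -> set[str]:
        return {" ".join(seq) for seq in self.stemmed.values()}

    def term_tag(self, term: str) -> str | None:
        return self.tags.get(term)

    def _build_index(self) -> None:
        # Separate indexes: unstemmed terms match unstemmed tokens only, and
        # stemmed terms match stemmed tokens only.
        indexes = []
        for mapping in (self.unstemmed, self.stemmed):
            index: dict[tuple[str, ...], set[str]] = {}
            for term, seq in mapping.items():
                index.setdefault(seq, set()).add(term)
            lengths = tuple(sorted({len(seq) for seq in index}))
            indexes.append((index, lengths))
        self._indexes = tuple(indexes)

    def exercise_terms(self) -> set[str]:
        return {t for t, tag in self.tags.items() if tag == "exercise"}


def _preprocess_term(term: str, stem: bool) -> tuple[str, ...]:
    tokens = remove_stopwords(tokenize(term))
    if stem:
        tokens = [porter_stem(t) for t in tokens]
    return tuple(tokens)


def load_dictionary(path: str | Path | None = None) -> TermDictionary:
    """Load a term dictionary (one term per line, optional TAB + tag).

    Without a path the bundled reconstructed starter dictionary is used.
    Terms are lowercased and deduplicated; blank lines and ``#`` comments are
    skipped; an empty file is an error.
    """
    if path is None:
        raw = resources.files("pdsocial.data").joinpath("pd_terms.tsv").read_text("utf-8")
    else:
        raw = Path(path).read_text("utf-8")

    tags: dict[str, str | None] = {}
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term, _, tag = line.partition("\t")
        term = term.strip().lower()
        tag = tag.strip().lower() or None
        if tag is not None and tag not in TAGS:
            raise ValueError(f"unknown dictionary tag {tag!r} for term {term!r}")
        if term in tags:
            log.info("duplicate dictionary term collapsed: %r", term)
            if tags[term] is None:
                tags[term] = tag
            continue
        tags[term] = tag
    if not tags:
        raise ValueError("term dictionary is empty")

    dictionary = TermDictionary(tags=tags)
    for term in list(tags):
        unstemmed = _preprocess_term(term, stem=False)
        if not unstemmed:
            log.warning("dictionary term %r is empty after preprocessing; dropped", term)
            del dictionary.tags[term]
            continue
        dictionary.unstemmed[term] = unstemmed
        dictionary.stemmed[term] = _preprocess_term(term, stem=True)
    dictionary._build_index()
    return dictionary


def preprocess_for_match(text: str) -> tuple[list[str], list[str]]:
    """Lowercase, strip punctuation, drop stop words; return (unstemmed, stemmed)."""
    tokens = remove_stopwords(tokenize(text))
    return tokens, [porter_stem(t) for t in tokens]


def dictionary_flag(
    text: str,
    dictionary: TermDictionary,
    tokens: tuple[list[str], list[str]] | None = None,
) -> tuple[bool, list[tuple[str, str | None]]]:
    """Flag a post if any dictionary term occurs, stemmed or unstemmed.

    Multi-word terms match as consecutive preprocessed tokens.  Returns the
    hit flag and the matched (term, tag) pairs, sorted by term.
    """
    if tokens is None:
        tokens = preprocess_for_match(text)
    unstemmed, stemmed = tokens
    matched: set[str] = set()
    for sequence, (index, lengths) in zip(
        (tuple(unstemmed), tuple(stemmed)), dictionary._indexes
    ):
        n = len(sequence)
        for length in lengths:
            if length > n:
                break
            for i in range(n - length + 1):
                hit = index.get(sequence[i : i + length])
                if hit:
                    matched.update(hit)
    matches = sorted((term, dictionary.tags[term]) for term in matched)
    return bool(matches), matches


def explicit_mention(text: str) -> tuple[bool, bool]:
    """Explicit-mention rules on raw text.

    Returns (parkinson, pd_abbrev): a case-insensitive "parkinson" substring,
    and a case-sensitive word-boundary "PD" (so "updated" is never a match).
    """
    return "parkinson" in text.lower(), _PD_ABBREV_RE.search(text) is not None
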