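"""Reading social-media export archives into a clean per-participant post stream.

A data export is a directory of JSON files (posts, comments, pages, groups)
whose contents overlap: the same authored text can appear in more than one
file, reshared "memory" posts carry an in-text "N years ago" stamp, and text
may arrive double-encoded (UTF-8 bytes mis-read as Latin-1).  This module
harvests every timestamped text, repairs the encoding, strips the relative
timestamps, and deduplicates: entries with identical timestamp and text
collapse to one, and a repeated text is kept only when at least 180 seconds
have elapsed since the most recently *retained* occurrence of that text, so
that deliberate reshares survive while export artifacts do not.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path

from .textproc import collapse_whitespace

log = logging.getLogger(__name__)

__all__ = [
    "RawEntry",
    "Post",
    "read_export",
    "normalize_encoding",
    "strip_memory_timestamps",
    "deduplicate",
    "make_post_id",
    "NEAR_DUPLICATE_WINDOW_S",
]

#: Minimum elapsed seconds between retained occurrences of the same text.
NEAR_DUPLICATE_WINDOW_S = 180

#: JSON keys whose string values are harvested as author text.
TEXT_KEYS = {"post": "post", "comment": "comment", "description": "caption", "title": "other"}


@dataclass(frozen=True)
class RawEntry:
    """A timestamped author text as found in an export file, pre-dedup."""

    participant_id: str
    timestamp: int
    text: str
    source_file: str
    kind: str = "other"


@dataclass(frozen=True)
class Post:
    """A deduplicated, cleaned author text."""

    post_id: str
    participant_id: str
    timestamp: int
    text: str
    kind: str = "other"


def make_post_id(participant_id: str, timestamp: int, text: str) -> str:
    """Stable post identifier: hash of participant, timestamp and clean text."""
    digest = hashlib.sha1(f"{participant_id}|{timestamp}|{text}".encode()).hexdigest()
    return digest[:16]


# ---------------------------------------------------------------------------
# Encoding repair
# ---------------------------------------------------------------------------


def _repair_once(text: str) -> str:
    for encoding in ("latin-1", "cp1252"):
        try:
            raw = text.encode(encoding)
        except UnicodeEncodeError:
            continue
        try:
            fixed = raw.decode("utf-8")
        except UnicodeDecodeError:
            continue
        return fixed
    return text


def normalize_encoding(text: str) -> str:
    """Best-effort repair of UTF-8-read-as-Latin-1 mojibake; idempotent.

    Repairs are applied to a fixpoint (nested corruption unwinds fully); text
    that cannot be repaired passes through.  Output is NFC-normalized.
    """
    prev = None
    guard = 32
    while text != prev and guard:
        prev = text
        text = unicodedata.normalize("NFC", _repair_once(text))
        guard -= 1
    return text


# ---------------------------------------------------------------------------
# Relative-timestamp ("memory") stripping
# ---------------------------------------------------------------------------

_NUMBER_WORDS = (
    "one|two|three|four|five|six|seven|eight|nine|ten|eleven|twelve"
)
_MEMORY_RE = re.compile(
    rf"\b(?:\d+|{_NUMBER_WORDS})\s+(?:years?|months?|days?)\s+ago\b[\s:;,.!\-–—]*",
    re.IGNORECASE,
)


def strip_memory_timestamps(text: str) -> str:
    """Remove relative-time phrases such as "3 years ago" from reshared memories.

    Only quantified phrases (digit or number word + year/month/day + "ago")
    are removed, together with trailing punctuation and whitespace; "I met
    her years ago" is left alone.
    """
    return _MEMORY_RE.sub("", text).strip()


def clean_text(text: str) -> str:
    """Full per-entry cleaning: encoding repair, memory strip, whitespace collapse."""
    return collapse_whitespace(strip_memory_timestamps(normalize_encoding(text)))


# ---------------------------------------------------------------------------
# Harvest
# ---------------------------------------------------------------------------


def _walk(node, timestamp, source, participant_id, out):
    if isinstance(node, dict):
        ts = node.get("timestamp")
        if isinstance(ts, (int, float)) and not isinstance(ts, bool):
            timestamp = int(ts)
        for key, value in node.items():
            if key in TEXT_KEYS and isinstance(value, str) and value.strip():
                if timestamp is not None and timestamp >= 0:
                    out.append(
                        RawEntry(participant_id, timestamp, value, source, TEXT_KEYS[key])
                    )
            else:
                _walk(value, timestamp, source, participant_id, out)
    elif isinstance(node, list):
        for item in node:
            _walk(item, timestamp, source, participant_id, out)


def read_export(directory: str | Path, participant_id: str | None = None) -> list[RawEntry]:
    """Harvest every timestamped author text from the JSON files of an archive.

    Walks every JSON value recursively; a text-bearing key (post, comment,
    description, title) yields one entry stamped with the nearest enclosing
    timestamp.  Texts without a timestamp are skipped (they cannot be
    phase-assigned).  Malformed files are logged and skipped; an archive of
    text-free files yields an empty list, which is valid.
    """
    directory = Path(directory)
    if participant_id is None:
        participant_id = directory.name
    entries: list[RawEntry] = []
    for path in sorted(directory.rglob("*.json")):
        try:
            payload = json.loads(path.read_text("utf-8"))
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            log.warning("skipping malformed JSON file %s: %s", path, exc)
            continue
        _walk(payload, None, str(path), participant_id, entries)
    return entries


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(entries: list[RawEntry]) -> list[Post]:
    """Collapse export duplicates for a single participant.

    1. Entries are cleaned (encoding, memory stamps, whitespace) and empty
       texts dropped.
    2. Entries with identical (timestamp, cleaned text) collapse to one.
    3. In time order, a repeated text is retained only if at least 180 s have
       elapsed since the most recently retained occurrence of that text;
       anchoring to retained occurrences makes chains deterministic.

    Text comparison is case-sensitive on the cleaned text.
    """
    cleaned: list[tuple[int, str, str, str]] = []
    for entry in entries:
        text = clean_text(entry.text)
        if not text:
            continue
        cleaned.append((entry.timestamp, text, entry.kind, entry.participant_id))

    cleaned.sort(key=lambda item: (item[0], item[1]))
    seen_exact: set[tuple[int, str]] = set()
    last_retained: dict[str, int] = {}
    posts: list[Post] = []
    for timestamp, text, kind, pid in cleaned:
        if (timestamp, text) in seen_exact:
            continue
        seen_exact.add((timestamp, text))
        previous = last_retained.get(text)
        if previous is not None and timestamp - previous < NEAR_DUPLICATE_WINDOW_S:
            continue
        last_retained[text] = timestamp
        posts.append(Post(make_post_id(pid, timestamp, text), pid, timestamp, text, kind))
    return posts
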