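"""Short-text cleaning, length filtering, keyword queries, and classifier input prep.

Cleaning is deterministic and order-fixed: lowercase, expand abbreviations,
strip characters outside ``[a-z0-9 ]``, collapse whitespace, split on
whitespace.  A "word" is a whitespace-delimited token of the cleaned text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RawDocument",
    "CleanedDocument",
    "KeywordQuery",
    "Vocabulary",
    "DEFAULT_ABBREVIATIONS",
    "DEFAULT_MIN_WORDS",
    "DEFAULT_MAX_LEN",
    "PAD_INDEX",
    "OOV_INDEX",
    "clean_text",
    "deduplicate",
    "filter_short",
    "build_vocabulary",
    "pad_or_truncate",
    "keyword_match",
    "load_default_queries",
]

DEFAULT_MIN_WORDS = 5  # documents with word_count <= this are dropped
DEFAULT_MAX_LEN = 45  # fixed classifier input length, in tokens

PAD_INDEX = 0
OOV_INDEX = 1

#: Default abbreviation/contraction expansions, applied after lowercasing.
#: Keys bounded by word characters are matched with word boundaries, so
#: "od" does not rewrite "god".  User-supplied maps override this default.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "'s": " is",
    "'re": " are",
    "'ve": " have",
    "'ll": " will",
    "'d": " would",
    "'m": " am",
    "n't": " not",
    "can't": "can not",
    "won't": "will not",
    "od": "overdose",
}

_KEEP_RE = re.compile(r"[^a-z0-9 ]+")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class RawDocument:
    """An unprocessed short text with an opaque identifier."""

    doc_id: str
    text: str
    author_id: str | None = None


@dataclass(frozen=True)
class CleanedDocument:
    """A cleaned token sequence; ``word_count`` always equals ``len(tokens)``."""

    doc_id: str
    tokens: tuple[str, ...]
    author_id: str | None = None

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class KeywordQuery:
    """A three-group phrase query: (OR group) AND (OR group) AND NOT (OR group)."""

    any_of: tuple[str, ...]
    require_all: tuple[str, ...] = ()
    negate_group: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.any_of or self.require_all or self.negate_group):
            raise ValueError("keyword query needs at least one non-empty group")
        for group in (self.any_of, self.require_all, self.negate_group):
            for phrase in group:
                if phrase != phrase.lower():
                    raise ValueError(f"query phrases must be lowercase: {phrase!r}")


def _abbrev_pattern(key: str) -> re.Pattern[str]:
    prefix = r"(?<!\w)" if key[0].isalnum() else ""
    suffix = r"(?!\w)" if key[-1].isalnum() else ""
    return re.compile(prefix + re.escape(key) + suffix)


def clean_text(
    raw: RawDocument | str,
    abbreviation_map: Mapping[str, str] | None = None,
    *,
    doc_id: str = "",
) -> CleanedDocument:
    """Clean one raw text into a :class:`CleanedDocument`.

    Order: lowercase -> expand abbreviations (longest key first) -> drop
    characters outside ``[a-z0-9 ]`` -> collapse whitespace -> split.
    Empty output is a valid document with ``word_count == 0``.
    """
    if isinstance(raw, str):
        raw = RawDocument(doc_id=doc_id, text=raw)
    mapping = DEFAULT_ABBREVIATIONS if abbreviation_map is None else abbreviation_map
    text = raw.text.lower()
    for key in sorted(mapping, key=len, reverse=True):
        text = _abbrev_pattern(key).sub(mapping[key], text)
    text = _KEEP_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    tokens = tuple(text.split()) if text else ()
    return CleanedDocument(doc_id=raw.doc_id, tokens=tokens, author_id=raw.author_id)


def deduplicate(corpus: Iterable[CleanedDocument]) -> list[CleanedDocument]:
    """Keep the first occurrence of each distinct token sequence, in order."""
    seen: set[tuple[str, ...]] = set()
    out = []
    for doc in corpus:
        if doc.tokens not in seen:
            seen.add(doc.tokens)
            out.append(doc)
    return out


def filter_short(
    corpus: Iterable[CleanedDocument], min_exclusive: int = DEFAULT_MIN_WORDS
) -> list[CleanedDocument]:
    """Retain exactly the documents with ``word_count > min_exclusive``."""
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    return [doc for doc in corpus if doc.word_count > min_exclusive]


@dataclass(frozen=True)
class Vocabulary:
    """Token -> positive index map; 0 is padding, 1 is out-of-vocabulary."""

    index: Mapping[str, int]

    def __len__(self) -> int:
        return (max(self.index.values()) + 1) if self.index else 2

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, OOV_INDEX)

    def to_json(self) -> str:
        return json.dumps(dict(self.index))

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(index=json.loads(payload))


def build_vocabulary(corpus: Iterable[CleanedDocument]) -> Vocabulary:
    """Assign indices 2, 3, ... to tokens in first-appearance order."""
    index: dict[str, int] = {}
    nxt = OOV_INDEX + 1
    for doc in corpus:
        for tok in doc.tokens:
            if tok not in index:
                index[tok] = nxt
                nxt += 1
    return Vocabulary(index=index)


def pad_or_truncate(
    doc: CleanedDocument, vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN
) -> list[int]:
    """Map tokens to indices, right-pad with 0 or truncate to ``max_len``."""
    idx = [vocab[t] for t in doc.tokens[:max_len]]
    idx.extend([PAD_INDEX] * (max_len - len(idx)))
    return idx


def _phrase_found(text: str, phrase: str, word_boundaries: bool) -> bool:
    if not word_boundaries:
        return phrase in text
    pattern = r"(?<!\w)" + re.escape(phrase) + r"(?!\w)"
    return re.search(pattern, text) is not None


def keyword_match(
    doc_text: str, query: KeywordQuery, *, word_boundaries: bool = True
) -> bool:
    """Evaluate the query against raw lowercased text.

    True iff some ``any_of`` phrase occurs, AND (``require_all`` is empty or
    some phrase of it occurs), AND no ``negate_group`` phrase occurs.
    Matching is case-insensitive; word-boundary-aware by default so that
    e.g. "prison" does not match inside "imprisonment".
    """
    text = doc_text.lower()
    if query.any_of and not any(
        _phrase_found(text, p, word_boundaries) for p in query.any_of
    ):
        return False
    if query.require_all and not any(
        _phrase_found(text, p, word_boundaries) for p in query.require_all
    ):
        return False
    if any(_phrase_found(text, p, word_boundaries) for p in query.negate_group):
        return False
    return True


def load_default_queries() -> dict[str, KeywordQuery]:
    """Load the packaged keyword queries (keys: ``ace``, ``nonace1``, ``nonace2``)."""
    payload = resources.files("acenet.data").joinpath("keywords.json").read_text()
    cfg = json.loads(payload)
    adversity = tuple(cfg["adversity_phrases"])

    def resolve(group) -> tuple[str, ...]:
        if group == "$ADVERSITY":
            return adversity
        return tuple(group)

    return {
        name: KeywordQuery(
            any_of=resolve(q["any_of"]),
            require_all=resolve(q["require_all"]),
            negate_group=resolve(q["negate_group"]),
        )
        for name, q in cfg["queries"].items()
    }
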