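"""Dictionary-based GO concept recognition over title + abstract.

Exact normalized phrase matching: lowercase, punctuation stripped, greedy
longest-match scanning left to right on token boundaries, non-overlapping
spans.  A phrase shared by several terms yields one mention per term at the
same span (span overlap is only permitted between identical spans).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import Document
from .ontology import GODag

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def normalize(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(m.group(0).lower() for m in _TOKEN_RE.finditer(text))


@dataclass(frozen=True)
class Mention:
    """One recognized concept occurrence; offsets index ``title + " " + abstract``."""

    term_id: str
    surface: str
    start: int
    end: int


@dataclass
class Dictionary:
    """Normalized phrase → term ids, plus the longest phrase length in tokens."""

    entries: dict[str, frozenset[str]]
    max_phrase_len: int


def build_dictionary(dag: GODag, include_synonyms: bool = False) -> Dictionary:
    """Index canonical names (and optionally synonyms) of non-obsolete terms."""
    entries: dict[str, set[str]] = {}
    for term in dag.terms.values():
        if term.obsolete:
            continue
        phrases = [term.name]
        if include_synonyms:
            phrases.extend(term.synonyms)
        for phrase in phrases:
            norm = normalize(phrase)
            if norm:
                entries.setdefault(norm, set()).add(term.term_id)
    max_len = max((len(p.split()) for p in entries), default=0)
    return Dictionary({p: frozenset(ids) for p, ids in entries.items()}, max_len)


def recognize(doc: Document, dictionary: Dictionary) -> list[Mention]:
    """Greedy longest-match, left-to-right, case-insensitive, token-aligned."""
    text = doc.text
    tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    mentions: list[Mention] = []
    i, n = 0, len(tokens)
    while i < n:
        matched = 0
        for length in range(min(dictionary.max_phrase_len, n - i), 0, -1):
            phrase = " ".join(tok for tok, _, _ in tokens[i : i + length])
            ids = dictionary.entries.get(phrase)
            if ids:
                start = tokens[i][1]
                end = tokens[i + length - 1][2]
                surface = text[start:end]
                for term_id in sorted(ids):  # deterministic for ambiguous phrases
                    mentions.append(Mention(term_id, surface, start, end))
                matched = length
                break
        i += matched or 1
    return mentions


def mentioned_term_ids(doc: Document, dictionary: Dictionary) -> frozenset[str]:
    return frozenset(m.term_id for m in recognize(doc, dictionary))
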