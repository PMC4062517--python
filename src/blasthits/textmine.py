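"""Text mining over deflines and query names.

Regex search selects the HSPs whose sequence defline (or query name)
contains a match; word-frequency tables count, per token, the number of
*unique* deflines containing it — the unit the description viewer
displays — with a fully configurable regex splitter.  A small set of named
regex templates covers the common searches without writing regex by hand.

The supported pattern language is the portable common subset of regex:
literals, character classes, anchors, quantifiers, alternation and groups,
as implemented by Python's ``re`` module.  Searches are case-insensitive
by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import RegexError
from .model import Dataset
from .selection import Selection

DEFAULT_SPLITTER = r"\s+"


def _compile(pattern: str, case_sensitive: bool) -> "re.Pattern[str]":
    flags = 0 if case_sensitive else re.IGNORECASE
    try:
        return re.compile(pattern, flags)
    except re.error as exc:
        pos = getattr(exc, "pos", None)
        where = f" at position {pos}" if pos is not None else ""
        raise RegexError(f"bad pattern {pattern!r}{where}: {exc.msg}") from exc


def search(
    d: Dataset,
    pattern: str,
    scope: str = "deflines",
    case_sensitive: bool = False,
) -> Selection:
    """All HSPs whose defline (or query name) contains a pattern match."""
    rx = _compile(pattern, case_sensitive)
    if scope == "deflines":
        matched = {sid for sid, seq in enumerate(d.sequences)
                   if rx.search(seq.defline)}
        members = frozenset(i for i, h in enumerate(d.hsps) if h.seq_id in matched)
    elif scope == "query_names":
        matched = {qid for qid, name in enumerate(d.queries) if rx.search(name)}
        members = frozenset(i for i, h in enumerate(d.hsps) if h.query_id in matched)
    else:
        raise ValueError(f"scope must be 'deflines' or 'query_names', got {scope!r}")
    return Selection(d, members)


def word_frequencies(
    d: Dataset,
    scope: str = "deflines",
    splitter_pattern: str = DEFAULT_SPLITTER,
    min_count: int = 1,
) -> list[tuple[str, int]]:
    """(word, unique-header count) table, count descending then word ascending.

    Each case-folded token counts once per defline (or query name) that
    contains it, matching the "unique headers" unit of the description
    viewer rather than per-HSP totals.
    """
    rx = _compile(splitter_pattern, case_sensitive=True)
    if scope == "deflines":
        texts = [seq.defline for seq in d.sequences]
    elif scope == "query_names":
        texts = list(d.queries)
    else:
        raise ValueError(f"scope must be 'deflines' or 'query_names', got {scope!r}")
    counts: dict[str, int] = {}
    for text in texts:
        tokens = {tok.casefold() for tok in rx.split(text) if tok}
        for tok in tokens:
            counts[tok] = counts.get(tok, 0) + 1
    table = [(w, n) for w, n in counts.items() if n >= min_count]
    table.sort(key=lambda wn: (-wn[1], wn[0]))
    return table


@dataclass(frozen=True)
class RegexTemplate:
    """A named pattern builder with a usage example."""

    name: str
    description: str
    example: str

    def build(self, *args: str) -> str:
        raise NotImplementedError


class _ContainsPhrase(RegexTemplate):
    def build(self, phrase: str) -> str:
        return re.escape(phrase)


class _StartsWith(RegexTemplate):
    def build(self, prefix: str) -> str:
        return "^" + re.escape(prefix)


class _WholeWord(RegexTemplate):
    def build(self, word: str) -> str:
        return r"\b" + re.escape(word) + r"\b"


class _AnyOfWords(RegexTemplate):
    def build(self, *words: str) -> str:
        if not words:
            raise RegexError("any-of-words needs at least one word")
        return r"\b(?:" + "|".join(re.escape(w) for w in words) + r")\b"


class _AccessionLike(RegexTemplate):
    def build(self) -> str:
        # RefSeq/GenBank-style tokens: XP_123456.1, NM_000546, AB012345
        return r"\b[A-Z]{1,3}_?\d{5,}(?:\.\d+)?\b"


def template_patterns() -> dict[str, RegexTemplate]:
    """Named regex templates demanding no prior regex knowledge."""
    templates = [
        _ContainsPhrase("contains-phrase",
                        "headers containing a phrase verbatim",
                        'build("cell adhesion") -> matches "…cell adhesion…"'),
        _StartsWith("starts-with",
                    "headers beginning with a prefix",
                    'build("gi|") -> matches "gi|123|…"'),
        _WholeWord("whole-word",
                   "a word bounded by non-word characters",
                   'build("kinase") -> matches "a kinase b", not "akinaseb"'),
        _AnyOfWords("any-of-words",
                    "any one of several words",
                    'build("bent", "titin") -> matches either word'),
        _AccessionLike("accession-like",
                       "sequence accession tokens (XP_123456.1 style)",
                       'build() -> matches "XP_123456.1"'),
    ]
    return {t.name: t for t in templates}
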