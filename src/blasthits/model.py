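"""Core in-memory model: HSPs, deduplicated datasets and source indexes.

A :class:`Dataset` mirrors one ``.bgr`` store: an ordered list of query
names, an ordered list of unique hit deflines (each optionally carrying an
NCBI TAXID) and a flat list of :class:`HSP` records referencing both by
dense integer ids.  The HSP is the atomic counting unit everywhere in this
package: one gapped local alignment with its statistics and coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import BlastHitsError

#: HSP attributes that interval axes and cell statistics may address.
NUMERIC_ATTRIBUTES = (
    "evalue",
    "bit_score",
    "raw_score",
    "identity_pct",
    "positive_pct",
    "align_len",
    "gaps",
)


@dataclass(frozen=True)
class HSP:
    """One high-scoring pair.

    Coordinates are 1-based inclusive and normalised so that start <= end on
    both sequences; the original orientation of reverse-strand nucleotide
    hits is recoverable from the sign of ``s_frame`` (or ``q_frame``).
    Frames are 0 when not applicable (protein-protein searches).
    """

    query_id: int
    seq_id: int
    evalue: float
    bit_score: float
    raw_score: int
    identity_pct: float
    positive_pct: float
    gaps: int
    align_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_frame: int = 0
    s_frame: int = 0

    def validate(self) -> None:
        if not (self.q_start <= self.q_end and self.s_start <= self.s_end):
            raise BlastHitsError(f"HSP coordinates not normalised: {self}")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise BlastHitsError(f"identity_pct out of range: {self.identity_pct}")
        if not (0.0 <= self.positive_pct <= 100.0):
            raise BlastHitsError(f"positive_pct out of range: {self.positive_pct}")
        if self.align_len < 1:
            raise BlastHitsError(f"align_len must be >= 1: {self.align_len}")
        if self.evalue < 0:
            raise BlastHitsError(f"evalue must be >= 0: {self.evalue}")
        if self.gaps < 0:
            raise BlastHitsError(f"gaps must be >= 0: {self.gaps}")


@dataclass
class SeqEntry:
    """One unique hit sequence: its full defline and an optional TAXID."""

    defline: str
    taxid: Optional[int] = None


@dataclass
class SourceIndex:
    """Where alignment text for each HSP lives.

    For text-dialect reports, ``spans[i]`` is the (start, end) byte range of
    the i-th HSP's stanza in the source file; for XML-dialect reports,
    ``triples[i]`` is the (qseq, midline, hseq) alignment stored inline.
    ``checksum`` is the SHA-1 of the source file at parse time.
    """

    dialect: str  # "text" | "xml"
    checksum: str
    spans: Optional[list[tuple[int, int]]] = None
    triples: Optional[list[tuple[str, str, str]]] = None


@dataclass
class Dataset:
    """Deduplicated queries + sequences + HSP list; the .bgr in-memory mirror."""

    queries: list[str] = field(default_factory=list)
    sequences: list[SeqEntry] = field(default_factory=list)
    hsps: list[HSP] = field(default_factory=list)
    source_path: Optional[str] = None
    source_index: Optional[SourceIndex] = None

    # -- lookups ---------------------------------------------------------
    def query_id(self, name: str) -> int:
        try:
            return self.queries.index(name)
        except ValueError:
            raise BlastHitsError(f"unknown query name: {name!r}") from None

    def seq_id(self, defline: str) -> int:
        for i, s in enumerate(self.sequences):
            if s.defline == defline:
                return i
        raise BlastHitsError(f"unknown defline: {defline!r}")

    def hsps_of_query(self, query_id: int) -> list[int]:
        return [i for i, h in enumerate(self.hsps) if h.query_id == query_id]

    def hsps_of_sequence(self, seq_id: int) -> list[int]:
        return [i for i, h in enumerate(self.hsps) if h.seq_id == seq_id]

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise BlastHitsError on breach."""
        if len(set(self.queries)) != len(self.queries):
            raise BlastHitsError("query names are not unique")
        deflines = [s.defline for s in self.sequences]
        if len(set(deflines)) != len(deflines):
            raise BlastHitsError("deflines are not unique")
        nq, ns = len(self.queries), len(self.sequences)
        for h in self.hsps:
            if not (0 <= h.query_id < nq):
                raise BlastHitsError(f"HSP references missing query_id {h.query_id}")
            if not (0 <= h.seq_id < ns):
                raise BlastHitsError(f"HSP references missing seq_id {h.seq_id}")
            h.validate()
        if self.source_index is not None:
            idx = self.source_index
            n = len(self.hsps)
            if idx.spans is not None and len(idx.spans) != n:
                raise BlastHitsError("source index spans do not match HSP count")
            if idx.triples is not None and len(idx.triples) != n:
                raise BlastHitsError("source index triples do not match HSP count")


def _hsp_numbers(h: HSP) -> tuple:
    return (
        h.evalue, h.bit_score, h.raw_score, h.identity_pct, h.positive_pct,
        h.gaps, h.align_len, h.q_start, h.q_end, h.s_start, h.s_end,
        h.q_frame, h.s_frame,
    )


def hsps_equal(a: HSP, b: HSP, rel_tol: float = 1e-9) -> bool:
    """Field-wise equality with relative tolerance on the real-valued fields."""
    for x, y in zip(_hsp_numbers(a), _hsp_numbers(b)):
        if isinstance(x, float) or isinstance(y, float):
            if not math.isclose(x, y, rel_tol=rel_tol, abs_tol=1e-12):
                return False
        elif x != y:
            return False
    return True


def datasets_equal(a: Dataset, b: Dataset, rel_tol: float = 1e-9) -> bool:
    """Canonical equality: same queries, sequences and HSP multiset.

    Both datasets are compared in canonical order (see
    :func:`blasthits.bgr_store.canonicalize`); source paths and indexes are
    not part of dataset identity.
    """
    from .bgr_store import canonicalize  # local import: avoid cycle

    ca, cb = canonicalize(a), canonicalize(b)
    if ca.queries != cb.queries:
        return False
    if [(s.defline, s.taxid) for s in ca.sequences] != [
        (s.defline, s.taxid) for s in cb.sequences
    ]:
        return False
    if len(ca.hsps) != len(cb.hsps):
        return False
    return all(hsps_equal(x, y, rel_tol) for x, y in zip(ca.hsps, cb.hsps))


def copy_dataset(d: Dataset) -> Dataset:
    """Deep-enough copy (HSPs are frozen; lists and entries are fresh)."""
    return Dataset(
        queries=list(d.queries),
        sequences=[replace(s) for s in d.sequences],
        hsps=list(d.hsps),
        source_path=d.source_path,
        source_index=d.source_index,
    )
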