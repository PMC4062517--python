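"""Clipboard semantics: sets of HSPs that can become new datasets.

A :class:`Selection` is a set of HSP indices into one parent dataset.
Selections combine with ordinary set algebra and persist only by being
materialised into a new :class:`~blasthits.model.Dataset` (and from there a
``.bgr`` file), which is what enables the iterative open/select/save
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParentMismatch
from .model import HSP, Dataset, SeqEntry


@dataclass(frozen=True)
class Selection:
    parent: Dataset
    members: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        n = len(self.parent.hsps)
        bad = [i for i in self.members if not (0 <= i < n)]
        if bad:
            raise ValueError(f"selection references invalid HSP indices: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def query_ids(self) -> frozenset[int]:
        return frozenset(self.parent.hsps[i].query_id for i in self.members)

    @property
    def seq_ids(self) -> frozenset[int]:
        return frozenset(self.parent.hsps[i].seq_id for i in self.members)


def select_all(d: Dataset) -> Selection:
    return Selection(d, frozenset(range(len(d.hsps))))


def combine(a: Selection, b: Selection, op: str) -> Selection:
    """union | intersect | subtract, on selections of the same parent."""
    if a.parent is not b.parent:
        raise ParentMismatch("selections have different parent datasets")
    if op == "union":
        members = a.members | b.members
    elif op == "intersect":
        members = a.members & b.members
    elif op == "subtract":
        members = a.members - b.members
    else:
        raise ValueError(f"unknown set operation {op!r}")
    return Selection(a.parent, members)


def to_dataset(s: Selection) -> Dataset:
    """Materialise a selection as a standalone dataset.

    Only queries and sequences referenced by member HSPs are carried over
    (zero-hit queries of the parent are therefore dropped); TAXIDs travel
    with their sequences and all ids are renumbered densely.
    """
    parent = s.parent
    members = sorted(s.members)
    q_map: dict[int, int] = {}
    s_map: dict[int, int] = {}
    out = Dataset()
    for i in members:
        h = parent.hsps[i]
        if h.query_id not in q_map:
            q_map[h.query_id] = len(out.queries)
            out.queries.append(parent.queries[h.query_id])
        if h.seq_id not in s_map:
            seq = parent.sequences[h.seq_id]
            s_map[h.seq_id] = len(out.sequences)
            out.sequences.append(SeqEntry(seq.defline, seq.taxid))
        out.hsps.append(HSP(**{**h.__dict__,
                               "query_id": q_map[h.query_id],
                               "seq_id": s_map[h.seq_id]}))
    out.validate()
    return out
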