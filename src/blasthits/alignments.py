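"""Span layouts and verbatim alignment extraction.

The graphical alignment views of the original workflow reduce to span
arithmetic on HSP coordinates: a *per-query* layout puts every HSP of one
query on the query's coordinate axis, and the inverse *per-hit* layout puts
every query's HSPs on one hit sequence's axis (e.g. genes along a
chromosome).  Only spans are represented — mismatches and gaps are not part
of the stored attributes.

Full alignment text is recovered from the original BLAST report: for text
reports the exact stanza bytes are returned via the byte-offset index
recorded at parse time (guarded by a checksum), and for XML reports the
qseq/midline/hseq triples stored inline are re-rendered.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .crosstab import Matrix
from .errors import (NoAlignment, SourceChanged, SourceMissing, UnknownQuery,
                     UnknownSequence)
from .model import Dataset


@dataclass(frozen=True)
class Track:
    """One HSP drawn on the anchor's coordinate axis."""

    partner: str
    start: int
    end: int
    evalue: float
    bit_score: float
    hsp_index: int
    heat: Optional[float] = None


@dataclass
class SpanLayout:
    """All HSPs of one anchor (a query or a hit sequence) as sorted spans."""

    anchor: str
    anchor_length: int  # max observed end when the true length is unknown
    tracks: list[Track] = field(default_factory=list)


def _build_layout(d: Dataset, anchor: str, hsp_ids: list[int], per_query: bool) -> SpanLayout:
    tracks = []
    for i in hsp_ids:
        h = d.hsps[i]
        if per_query:
            start, end = h.q_start, h.q_end
            partner = d.sequences[h.seq_id].defline
        else:
            start, end = h.s_start, h.s_end
            partner = d.queries[h.query_id]
        tracks.append(Track(partner=partner, start=start, end=end,
                            evalue=h.evalue, bit_score=h.bit_score, hsp_index=i))
    tracks.sort(key=lambda t: (t.start, -t.bit_score, t.partner))
    length = max((t.end for t in tracks), default=1)
    return SpanLayout(anchor=anchor, anchor_length=length, tracks=tracks)


def layout_for_query(d: Dataset, query_name: str) -> SpanLayout:
    """One track per HSP of the query, on query coordinates."""
    try:
        qid = d.queries.index(query_name)
    except ValueError:
        raise UnknownQuery(f"no query named {query_name!r}") from None
    return _build_layout(d, query_name, d.hsps_of_query(qid), per_query=True)


def layout_for_hit(d: Dataset, defline: str) -> SpanLayout:
    """One track per HSP hitting the sequence, on subject coordinates."""
    sid = next((k for k, s in enumerate(d.sequences) if s.defline == defline), None)
    if sid is None:
        raise UnknownSequence(f"no sequence with defline {defline!r}")
    return _build_layout(d, defline, d.hsps_of_sequence(sid), per_query=False)


def apply_heat(layout: SpanLayout, matrix: Matrix) -> SpanLayout:
    """Attach the matrix's normalised cell value to each track's HSP.

    Shares the crosstab normalisation code path: build a heat-map matrix on
    the attribute of interest, then colour tracks by the value of the cell
    their HSP landed in.
    """
    by_hsp: dict[int, float] = {}
    for rc, members in matrix.cells.items():
        for i in members:
            by_hsp[i] = matrix.values[rc]
    layout.tracks = [
        Track(partner=t.partner, start=t.start, end=t.end, evalue=t.evalue,
              bit_score=t.bit_score, hsp_index=t.hsp_index,
              heat=by_hsp.get(t.hsp_index))
        for t in layout.tracks
    ]
    return layout


def layout_to_bed(layout: SpanLayout) -> str:
    """BED-like TSV: anchor, start-1, end, partner, bit score.

    Internal coordinates are 1-based inclusive; output is 0-based half-open.
    """
    lines = [
        f"{layout.anchor}\t{t.start - 1}\t{t.end}\t{t.partner}\t{t.bit_score:g}"
        for t in layout.tracks
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Verbatim extraction
# ---------------------------------------------------------------------------


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def extract_alignment_text(d: Dataset, query_name: str, defline: str) -> str:
    """Alignment text for every HSP of one (query, hit) pair.

    Text-dialect sources return the exact stanza bytes from the original
    report (each stanza a contiguous verbatim substring); XML-dialect
    sources return the stored qseq/midline/hseq triples.  The source file
    must still exist and match the checksum recorded at parse time.
    """
    try:
        qid = d.queries.index(query_name)
    except ValueError:
        raise UnknownQuery(f"no query named {query_name!r}") from None
    sid = next((k for k, s in enumerate(d.sequences) if s.defline == defline), None)
    if sid is None:
        raise UnknownSequence(f"no sequence with defline {defline!r}")
    hsp_ids = [i for i, h in enumerate(d.hsps)
               if h.query_id == qid and h.seq_id == sid]
    if not hsp_ids:
        raise NoAlignment(f"no HSP for {query_name!r} vs {defline!r}")
    idx = d.source_index
    if idx is None or d.source_path is None:
        raise SourceMissing("dataset carries no source index "
                            "(parse the original BLAST report to extract alignments)")

    if idx.dialect == "text":
        path = Path(d.source_path)
        if not path.exists():
            raise SourceMissing(f"source report {path} is gone")
        if _sha1(path) != idx.checksum:
            raise SourceChanged(f"source report {path} changed since parsing")
        data = path.read_bytes()
        blocks = [data[idx.spans[i][0]:idx.spans[i][1]].decode("utf-8", errors="replace")
                  for i in hsp_ids]
        return "".join(blocks)

    # XML dialect: re-render the stored alignment triples
    out: list[str] = []
    for i in hsp_ids:
        qseq, midline, hseq = idx.triples[i]
        h = d.hsps[i]
        out.append(f" Score = {h.bit_score:.1f} bits ({h.raw_score}),  "
                   f"Expect = {h.evalue:g}\n")
        for off in range(0, len(qseq), 60):
            out.append(f"Query  {qseq[off:off + 60]}\n")
            out.append(f"       {midline[off:off + 60]}\n")
            out.append(f"Sbjct  {hseq[off:off + 60]}\n\n")
    return "".join(out)
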