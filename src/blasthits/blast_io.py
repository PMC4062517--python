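"""Parse BLAST reports (classic pairwise text and XML) into a Dataset.

Both parsers produce the same canonical content for the same search:

* one query per ``Query=`` block / ``<Iteration>``, zero-hit queries kept;
* one sequence entry per *unique* full defline — hit sequences appearing
  under several queries are stored once;
* one :class:`~blasthits.model.HSP` per HSP stanza / ``<Hsp>`` element, with
  identity and positive percentages recomputed from the integer fraction
  counts (never read from the rounded printed percent) and reverse-strand
  coordinates normalised to ascending with the orientation kept in the
  frame sign.

The text parser additionally records the byte span of every HSP stanza so
that alignment text can later be extracted verbatim from the source report;
the XML parser stores the qseq/midline/hseq triples that the format carries
inline.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Iterator, Optional

from lxml import etree

from .errors import ParseError, UnrecognizedFormat
from .model import HSP, Dataset, SeqEntry, SourceIndex

_TEXT_BANNER = re.compile(r"^(BLASTN|BLASTP|BLASTX|TBLASTN|TBLASTX)\s+\S+")
_XML_SIGNATURE = re.compile(rb"^\s*<(\?xml|!DOCTYPE\s+BlastOutput|BlastOutput)")


def detect_format(path) -> str:
    """Return ``"xml"`` or ``"text"``; raise UnrecognizedFormat otherwise.

    XML is recognised by an XML declaration or a ``<BlastOutput`` element in
    the first non-blank bytes; text by a BLAST program banner (``BLASTP
    2.2.26+`` etc.) on the first non-blank of the leading 50 lines.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        for lineno, raw in enumerate(fh):
            if lineno >= 50:
                break
            line = raw.strip()
            if not line:
                continue
            if _XML_SIGNATURE.match(line):
                return "xml"
            try:
                text = line.decode("utf-8", errors="replace")
            except Exception:  # pragma: no cover - decode never raises here
                break
            if _TEXT_BANNER.match(text):
                return "text"
            break  # first non-blank line decides
    raise UnrecognizedFormat(f"{path}: neither BLAST XML nor classic text output")


def parse_report(path) -> Dataset:
    """Dispatch on :func:`detect_format`."""
    return parse_blast_xml(path) if detect_format(path) == "xml" else parse_blast_text(path)


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_GENERIC_ID = re.compile(r"^(gnl\|BL_ORD_ID\||lcl\|)")


def _join_defline(hit_id: str, hit_def: str) -> str:
    """Dedup key: Hit_id + " " + Hit_def, unless Hit_id is a generic local id."""
    hit_id = (hit_id or "").strip()
    hit_def = (hit_def or "").strip()
    if not hit_id or _GENERIC_ID.match(hit_id) or hit_id == hit_def:
        return hit_def or hit_id
    if not hit_def:
        return hit_id
    return f"{hit_id} {hit_def}"


def _text(elem, tag: str, default: Optional[str] = None) -> Optional[str]:
    child = elem.find(tag)
    if child is None or child.text is None:
        return default
    return child.text


def parse_blast_xml(path) -> Dataset:
    """Streaming parse of NCBI BLAST XML (one Iteration per query)."""
    path = Path(path)
    d = Dataset(source_path=str(path))
    seq_ids: dict[str, int] = {}
    triples: list[tuple[str, str, str]] = []
    try:
        context = etree.iterparse(
            str(path), events=("end",), tag="Iteration",
            load_dtd=False, no_network=True, resolve_entities=False,
        )
        for _, iteration in context:
            qname = _text(iteration, "Iteration_query-def")
            if qname is None:
                qname = _text(iteration, "Iteration_query-ID", "")
            qname = qname.strip()
            if qname in d.queries:
                raise ParseError(f"{path}: duplicate query name {qname!r}")
            qid = len(d.queries)
            d.queries.append(qname)
            hits = iteration.find("Iteration_hits")
            for hit in hits.findall("Hit") if hits is not None else ():
                defline = _join_defline(_text(hit, "Hit_id", ""), _text(hit, "Hit_def", ""))
                sid = seq_ids.get(defline)
                if sid is None:
                    sid = seq_ids[defline] = len(d.sequences)
                    d.sequences.append(SeqEntry(defline))
                hsps = hit.find("Hit_hsps")
                for hsp in hsps.findall("Hsp") if hsps is not None else ():
                    d.hsps.append(_xml_hsp(hsp, qid, sid, path))
                    triples.append((
                        _text(hsp, "Hsp_qseq", "") or "",
                        _text(hsp, "Hsp_midline", "") or "",
                        _text(hsp, "Hsp_hseq", "") or "",
                    ))
            iteration.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    d.source_index = SourceIndex(dialect="xml", checksum=_sha1(path), triples=triples)
    d.validate()
    return d


def _xml_int(hsp, tag: str, path, default: Optional[int] = None) -> int:
    value = _text(hsp, tag)
    if value is None:
        if default is not None:
            return default
        raise ParseError(f"{path}: <Hsp> missing <{tag}>")
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"{path}: bad integer in <{tag}>: {value!r}") from exc


def _xml_hsp(hsp, qid: int, sid: int, path) -> HSP:
    try:
        evalue = float(_text(hsp, "Hsp_evalue"))
        bit_score = float(_text(hsp, "Hsp_bit-score"))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: bad <Hsp> statistics: {exc}") from exc
    align_len = _xml_int(hsp, "Hsp_align-len", path)
    identity = _xml_int(hsp, "Hsp_identity", path)
    positive = _xml_int(hsp, "Hsp_positive", path, default=0)
    gaps = _xml_int(hsp, "Hsp_gaps", path, default=0)
    q_from = _xml_int(hsp, "Hsp_query-from", path)
    q_to = _xml_int(hsp, "Hsp_query-to", path)
    s_from = _xml_int(hsp, "Hsp_hit-from", path)
    s_to = _xml_int(hsp, "Hsp_hit-to", path)
    q_frame = _xml_int(hsp, "Hsp_query-frame", path, default=0)
    s_frame = _xml_int(hsp, "Hsp_hit-frame", path, default=0)
    if q_from > q_to:
        q_from, q_to = q_to, q_from
        if q_frame >= 0:
            q_frame = -1
    if s_from > s_to:
        s_from, s_to = s_to, s_from
        if s_frame >= 0:
            s_frame = -1
    return HSP(
        query_id=qid, seq_id=sid,
        evalue=evalue, bit_score=bit_score,
        raw_score=_xml_int(hsp, "Hsp_score", path),
        identity_pct=100.0 * identity / align_len,
        positive_pct=100.0 * positive / align_len,
        gaps=gaps, align_len=align_len,
        q_start=q_from, q_end=q_to, s_start=s_from, s_end=s_to,
        q_frame=q_frame, s_frame=s_frame,
    )


# ---------------------------------------------------------------------------
# Classic text dialect
# ---------------------------------------------------------------------------

_RE_QUERY = re.compile(r"^Query=\s*(.*)$")
_RE_DEFLINE = re.compile(r"^>(.*)$")
_RE_LENGTH = re.compile(r"^\s*Length\s*=?\s*[\d,]+")
_RE_SCORE = re.compile(
    r"^\s*Score\s*=\s*([0-9.eE+-]+)\s*bits\s*\((\d+)\)"
    r"(?:,\s*Expect(?:\(\d+\))?\s*=\s*(\S+?),?\s*(?:Method.*)?)?\s*$"
)
_RE_EXPECT = re.compile(r"Expect(?:\(\d+\))?\s*=\s*(\S+?),?\s*$")
_RE_IDENTITIES = re.compile(r"Identities\s*=\s*(\d+)/(\d+)")
_RE_POSITIVES = re.compile(r"Positives\s*=\s*(\d+)/(\d+)")
_RE_GAPS = re.compile(r"Gaps\s*=\s*(\d+)/(\d+)")
_RE_FRAME = re.compile(r"^\s*Frame\s*=\s*([+-]\d)(?:\s*/\s*([+-]\d))?\s*$")
_RE_STRAND = re.compile(r"^\s*Strand\s*=\s*(Plus|Minus)\s*/\s*(Plus|Minus)\s*$")
_RE_COORD = re.compile(r"^(Query|Sbjct):?\s+(\d+)\s+([A-Za-z*\-]+)\s+(\d+)\s*$")
_RE_FOOTER = re.compile(r"^(Lambda\b|\s{1,4}Database:|Matrix:|Gapped\b|Effective\b)")
_RE_NO_HITS = re.compile(r"No hits found")


def _parse_evalue(token: str) -> float:
    token = token.rstrip(",")
    if token.startswith(("e", "E")):  # old BLAST prints "e-100" for 1e-100
        token = "1" + token
    return float(token)


class _PendingHsp:
    """Mutable accumulator for one text HSP stanza."""

    __slots__ = (
        "offset", "bit_score", "raw_score", "evalue", "identity", "positive",
        "gaps", "align_len", "q_frame", "s_frame", "q_coords", "s_coords",
        "s_descending", "q_descending",
    )

    def __init__(self, offset: int):
        self.offset = offset
        self.bit_score = self.evalue = None
        self.raw_score = None
        self.identity = self.positive = self.gaps = None
        self.align_len = None
        self.q_frame = self.s_frame = 0
        self.q_coords: list[int] = []
        self.s_coords: list[int] = []
        self.s_descending = False
        self.q_descending = False


class _TextParser:
    def __init__(self, path: Path):
        self.path = path
        self.d = Dataset(source_path=str(path))
        self.seq_ids: dict[str, int] = {}
        self.spans: list[tuple[int, int]] = []
        self.program: Optional[str] = None
        self.qid: Optional[int] = None
        self.sid: Optional[int] = None
        self.pending: Optional[_PendingHsp] = None
        self.pending_defline: Optional[list[str]] = None

    def error(self, lineno: int, msg: str) -> ParseError:
        return ParseError(f"{self.path}:{lineno}: {msg}")

    # -- stanza lifecycle ------------------------------------------------
    def flush_hsp(self, end_offset: int, lineno: int) -> None:
        p = self.pending
        if p is None:
            return
        self.pending = None
        if p.bit_score is None or p.evalue is None:
            raise self.error(lineno, "HSP stanza missing Score/Expect")
        if p.identity is None or p.align_len is None:
            raise self.error(lineno, "HSP stanza missing Identities")
        if not p.q_coords or not p.s_coords:
            raise self.error(lineno, "HSP stanza missing alignment coordinate lines")
        if self.qid is None or self.sid is None:
            raise self.error(lineno, "HSP stanza outside a query/hit block")
        q_start, q_end = min(p.q_coords), max(p.q_coords)
        s_start, s_end = min(p.s_coords), max(p.s_coords)
        q_frame, s_frame = p.q_frame, p.s_frame
        if p.q_descending and q_frame >= 0:
            q_frame = -1
        if p.s_descending and s_frame >= 0:
            s_frame = -1
        self.d.hsps.append(HSP(
            query_id=self.qid, seq_id=self.sid,
            evalue=p.evalue, bit_score=p.bit_score, raw_score=p.raw_score,
            identity_pct=100.0 * p.identity / p.align_len,
            positive_pct=(100.0 * p.positive / p.align_len) if p.positive is not None else 0.0,
            gaps=p.gaps or 0, align_len=p.align_len,
            q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
            q_frame=q_frame, s_frame=s_frame,
        ))
        self.spans.append((p.offset, end_offset))

    def flush_defline(self) -> None:
        if self.pending_defline is None:
            return
        defline = " ".join(part.strip() for part in self.pending_defline).strip()
        self.pending_defline = None
        sid = self.seq_ids.get(defline)
        if sid is None:
            sid = self.seq_ids[defline] = len(self.d.sequences)
            self.d.sequences.append(SeqEntry(defline))
        self.sid = sid

    # -- main loop -------------------------------------------------------
    def parse(self) -> Dataset:
        with open(self.path, "rb") as fh:
            data = fh.read()
        offset = 0
        lines: list[tuple[int, int, str]] = []  # (offset, lineno, text)
        for lineno, raw in enumerate(data.splitlines(keepends=True), start=1):
            lines.append((offset, lineno, raw.decode("utf-8", errors="replace").rstrip("\r\n")))
            offset += len(raw)
        end_of_file = offset

        saw_banner = False
        for off, lineno, line in lines:
            stripped = line.strip()
            if not saw_banner:
                if not stripped:
                    continue
                if not _TEXT_BANNER.match(stripped):
                    raise self.error(lineno, "missing BLAST program banner")
                self.program = stripped.split()[0]
                saw_banner = True
                continue

            m = _RE_QUERY.match(line)
            if m:
                self.flush_hsp(off, lineno)
                self.flush_defline()
                name = m.group(1).strip()
                if name in self.d.queries:
                    raise self.error(lineno, f"duplicate query name {name!r}")
                self.qid = len(self.d.queries)
                self.d.queries.append(name)
                self.sid = None
                continue

            if self.pending_defline is not None:
                # defline may wrap onto continuation lines until Length=/blank
                if stripped and not _RE_LENGTH.match(line):
                    self.pending_defline.append(line)
                    continue
                self.flush_defline()
                continue

            m = _RE_DEFLINE.match(line)
            if m:
                self.flush_hsp(off, lineno)
                self.pending_defline = [m.group(1)]
                continue

            m = _RE_SCORE.match(line)
            if m:
                self.flush_hsp(off, lineno)
                if self.qid is None:
                    raise self.error(lineno, "Score line outside a query block")
                p = _PendingHsp(off)
                p.bit_score = float(m.group(1))
                p.raw_score = int(m.group(2))
                if m.group(3):
                    p.evalue = _parse_evalue(m.group(3))
                else:
                    em = _RE_EXPECT.search(line)
                    if em:
                        p.evalue = _parse_evalue(em.group(1))
                self.pending = p
                continue

            if _RE_FOOTER.match(line):
                self.flush_hsp(off, lineno)
                continue

            p = self.pending
            if p is None:
                continue

            if p.evalue is None:
                em = _RE_EXPECT.search(line)
                if em:
                    p.evalue = _parse_evalue(em.group(1))
                    continue

            m = _RE_IDENTITIES.search(line)
            if m:
                p.identity, p.align_len = int(m.group(1)), int(m.group(2))
                pm = _RE_POSITIVES.search(line)
                if pm:
                    p.positive = int(pm.group(1))
                gm = _RE_GAPS.search(line)
                if gm:
                    p.gaps = int(gm.group(1))
                continue

            m = _RE_GAPS.search(line)
            if m and p.gaps is None and not _RE_COORD.match(line):
                p.gaps = int(m.group(1))
                continue

            m = _RE_STRAND.match(line)
            if m:
                p.q_frame = 1 if m.group(1) == "Plus" else -1
                p.s_frame = 1 if m.group(2) == "Plus" else -1
                continue

            m = _RE_FRAME.match(line)
            if m:
                first = int(m.group(1))
                second = int(m.group(2)) if m.group(2) else None
                if second is not None:  # tblastx: query/subject
                    p.q_frame, p.s_frame = first, second
                elif self.program == "BLASTX":
                    p.q_frame = first
                else:  # TBLASTN and friends: subject frame
                    p.s_frame = first
                continue

            m = _RE_COORD.match(line)
            if m:
                which, start, end = m.group(1), int(m.group(2)), int(m.group(4))
                if which == "Query":
                    if start > end:
                        p.q_descending = True
                    p.q_coords.extend((start, end))
                else:
                    if start > end:
                        p.s_descending = True
                    p.s_coords.extend((start, end))
                continue

        self.flush_hsp(end_of_file, len(lines))
        self.flush_defline()
        if not saw_banner:
            raise ParseError(f"{self.path}: empty file, no BLAST banner")
        self.d.source_index = SourceIndex(
            dialect="text", checksum=hashlib.sha1(data).hexdigest(), spans=self.spans,
        )
        self.d.validate()
        return self.d


def parse_blast_text(path) -> Dataset:
    """Parse a classic pairwise text report (BLAST 2.2.* or BLAST+ banners)."""
    return _TextParser(Path(path)).parse()


def iter_query_blocks_text(data: bytes) -> Iterator[tuple[int, int]]:
    """Byte spans of each ``Query=`` block (used by the report splitter)."""
    starts = [m.start() for m in re.finditer(rb"(?m)^Query=", data)]
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else len(data)
        yield start, end
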