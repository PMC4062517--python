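"""The ``.bgr`` dataset store: a frozen, versioned text interchange format.

Layout (UTF-8, tab-separated, ``#``-prefixed section headers carrying row
counts)::

    #BGR1
    #QUERIES <n>
    <query_id>\t<name>
    #SEQUENCES <n>
    <seq_id>\t<defline>\t<taxid or empty>
    #HSPS <n>
    <query_id>\t<seq_id>\t<evalue>\t<bit_score>\t<raw_score>\t<identity_pct>
        \t<positive_pct>\t<gaps>\t<align_len>\t<q_start>\t<q_end>
        \t<s_start>\t<s_end>\t<q_frame>\t<s_frame>

Floats are written with ``repr`` so write/read is lossless, and writing the
same dataset twice yields byte-identical files.  ``merge_datasets`` unifies
queries by exact name and sequences by exact defline (keeping one copy per
the dedup rule) while HSP rows are concatenated losslessly — merging the
parts of a split report must reproduce the original.  ``canonicalize``
defines the order-independent normal form used as the equality basis of
every round-trip check.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from . import blast_io
from .errors import FormatError, TaxidConflict, UnrecognizedFormat, VersionError
from .model import HSP, Dataset, SeqEntry

MAGIC = "#BGR1"

_HSP_FIELDS = (
    "query_id", "seq_id", "evalue", "bit_score", "raw_score", "identity_pct",
    "positive_pct", "gaps", "align_len", "q_start", "q_end", "s_start",
    "s_end", "q_frame", "s_frame",
)
_HSP_TYPES = (int, int, float, float, int, float, float, int, int, int, int,
              int, int, int, int)


def write_bgr(d: Dataset, path) -> Path:
    """Serialize a dataset; deterministic bytes for identical content."""
    d.validate()
    path = Path(path)
    lines = [MAGIC, f"#QUERIES {len(d.queries)}"]
    for qid, name in enumerate(d.queries):
        lines.append(f"{qid}\t{name}")
    lines.append(f"#SEQUENCES {len(d.sequences)}")
    for sid, seq in enumerate(d.sequences):
        taxid = "" if seq.taxid is None else str(seq.taxid)
        lines.append(f"{sid}\t{seq.defline}\t{taxid}")
    lines.append(f"#HSPS {len(d.hsps)}")
    for h in d.hsps:
        values = [getattr(h, f) for f in _HSP_FIELDS]
        lines.append("\t".join(repr(v) if isinstance(v, float) else str(v)
                               for v in values))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_bgr(path) -> Dataset:
    """Load a ``.bgr`` file fully into memory."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}:1: empty file")
    if lines[0] != MAGIC:
        raise VersionError(f"{path}:1: unknown format header {lines[0]!r}")
    d = Dataset()
    i = 1

    def section(tag: str) -> int:
        nonlocal i
        if i >= len(lines) or not lines[i].startswith(f"#{tag} "):
            raise FormatError(f"{path}:{i + 1}: expected #{tag} section header")
        try:
            count = int(lines[i].split(" ", 1)[1])
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: bad count in #{tag} header") from None
        i += 1
        return count

    nq = section("QUERIES")
    for k in range(nq):
        lineno = i + 1
        if i >= len(lines):
            raise FormatError(f"{path}:{lineno}: query section truncated")
        fields = lines[i].split("\t")
        if len(fields) != 2 or fields[0] != str(k):
            raise FormatError(f"{path}:{lineno}: bad query row")
        d.queries.append(fields[1])
        i += 1

    ns = section("SEQUENCES")
    for k in range(ns):
        lineno = i + 1
        if i >= len(lines):
            raise FormatError(f"{path}:{lineno}: sequence section truncated")
        fields = lines[i].split("\t")
        if len(fields) != 3 or fields[0] != str(k):
            raise FormatError(f"{path}:{lineno}: bad sequence row")
        taxid = int(fields[2]) if fields[2] else None
        d.sequences.append(SeqEntry(fields[1], taxid))
        i += 1

    nh = section("HSPS")
    for _ in range(nh):
        lineno = i + 1
        if i >= len(lines):
            raise FormatError(f"{path}:{lineno}: HSP section truncated")
        fields = lines[i].split("\t")
        if len(fields) != len(_HSP_FIELDS):
            raise FormatError(f"{path}:{lineno}: expected {len(_HSP_FIELDS)} columns")
        try:
            values = [t(v) for t, v in zip(_HSP_TYPES, fields)]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad HSP value: {exc}") from None
        d.hsps.append(HSP(**dict(zip(_HSP_FIELDS, values))))
        i += 1

    if any(line.strip() for line in lines[i:]):
        raise FormatError(f"{path}:{i + 1}: trailing content after HSP section")
    try:
        d.validate()
    except Exception as exc:
        raise FormatError(f"{path}: invalid dataset: {exc}") from exc
    return d


# ---------------------------------------------------------------------------
# Canonical form and merging
# ---------------------------------------------------------------------------


def canonicalize(d: Dataset) -> Dataset:
    """Order-independent normal form: sorted queries, deflines and HSPs.

    HSPs sort by (query name, defline, q_start, s_start, bit_score desc);
    ids are renumbered densely.  Idempotent.  The source index (byte
    offsets/alignment triples) is dropped, since it is tied to the original
    HSP order.
    """
    q_order = sorted(range(len(d.queries)), key=lambda q: d.queries[q])
    s_order = sorted(range(len(d.sequences)), key=lambda s: d.sequences[s].defline)
    q_map = {old: new for new, old in enumerate(q_order)}
    s_map = {old: new for new, old in enumerate(s_order)}
    out = Dataset(
        queries=[d.queries[q] for q in q_order],
        sequences=[SeqEntry(d.sequences[s].defline, d.sequences[s].taxid)
                   for s in s_order],
    )
    def key(h: HSP):
        return (d.queries[h.query_id], d.sequences[h.seq_id].defline,
                h.q_start, h.s_start, -h.bit_score)

    for h in sorted(d.hsps, key=key):
        out.hsps.append(HSP(**{**h.__dict__,
                               "query_id": q_map[h.query_id],
                               "seq_id": s_map[h.seq_id]}))
    return out


def merge_datasets(datasets: Iterable[Dataset]) -> Dataset:
    """Union of datasets: queries by name, sequences by defline, HSPs appended.

    Exact duplicate HSP rows are retained so that merging the parts of a
    split report is lossless.  A defline carrying two different TAXIDs
    across inputs raises TaxidConflict.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("merge_datasets requires at least one dataset")
    out = Dataset()
    q_index: dict[str, int] = {}
    s_index: dict[str, int] = {}
    for d in datasets:
        q_map: dict[int, int] = {}
        for qid, name in enumerate(d.queries):
            if name not in q_index:
                q_index[name] = len(out.queries)
                out.queries.append(name)
            q_map[qid] = q_index[name]
        s_map: dict[int, int] = {}
        for sid, seq in enumerate(d.sequences):
            if seq.defline not in s_index:
                s_index[seq.defline] = len(out.sequences)
                out.sequences.append(SeqEntry(seq.defline, seq.taxid))
            else:
                existing = out.sequences[s_index[seq.defline]]
                if seq.taxid is not None:
                    if existing.taxid is None:
                        existing.taxid = seq.taxid
                    elif existing.taxid != seq.taxid:
                        raise TaxidConflict(
                            f"defline {seq.defline!r} carries TAXIDs "
                            f"{existing.taxid} and {seq.taxid}"
                        )
            s_map[sid] = s_index[seq.defline]
        for h in d.hsps:
            out.hsps.append(HSP(**{**h.__dict__,
                                   "query_id": q_map[h.query_id],
                                   "seq_id": s_map[h.seq_id]}))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Splitting raw BLAST reports
# ---------------------------------------------------------------------------


def _part_sizes(n_items: int, n_parts: int) -> list[int]:
    n_parts = min(n_parts, n_items) or 1
    base, extra = divmod(n_items, n_parts)
    return [base + (1 if k < extra else 0) for k in range(n_parts)]


def split_blast_file(path, n_parts: int, out_dir: Optional[Path] = None) -> list[Path]:
    """Split a raw BLAST report into independently parseable parts.

    Query blocks are never divided; parts keep the original query order and
    their sizes differ by at most one query.  Text parts reuse the original
    header bytes; XML parts are re-wrapped with the original header/footer
    elements.  ``n_parts`` beyond the query count degrades to one part per
    query.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be positive")
    path = Path(path)
    out_dir = Path(out_dir) if out_dir is not None else path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    dialect = blast_io.detect_format(path)
    if dialect == "text":
        return _split_text(path, n_parts, out_dir)
    return _split_xml(path, n_parts, out_dir)


def _split_text(path: Path, n_parts: int, out_dir: Path) -> list[Path]:
    data = path.read_bytes()
    blocks = list(blast_io.iter_query_blocks_text(data))
    if not blocks:
        raise UnrecognizedFormat(f"{path}: no Query= blocks found")
    header = data[: blocks[0][0]]
    paths: list[Path] = []
    pos = 0
    for k, size in enumerate(_part_sizes(len(blocks), n_parts), start=1):
        start = blocks[pos][0]
        end = blocks[pos + size - 1][1]
        pos += size
        part = out_dir / f"{path.stem}.part{k:03d}{path.suffix or '.txt'}"
        part.write_bytes(header + data[start:end])
        paths.append(part)
    return paths


def _split_xml(path: Path, n_parts: int, out_dir: Path) -> list[Path]:
    from lxml import etree

    from .errors import ParseError

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    iterations_el = root.find("BlastOutput_iterations")
    if iterations_el is None:
        raise ParseError(f"{path}: no <BlastOutput_iterations>")
    iterations = iterations_el.findall("Iteration")
    if not iterations:
        raise ParseError(f"{path}: no <Iteration> elements")
    paths: list[Path] = []
    pos = 0
    for k, size in enumerate(_part_sizes(len(iterations), n_parts), start=1):
        chunk = iterations[pos:pos + size]
        pos += size
        part_root = etree.Element(root.tag)
        for child in root:
            if child.tag != "BlastOutput_iterations":
                part_root.append(etree.fromstring(etree.tostring(child)))
        container = etree.SubElement(part_root, "BlastOutput_iterations")
        for it in chunk:
            container.append(etree.fromstring(etree.tostring(it)))
        part = out_dir / f"{path.stem}.part{k:03d}{path.suffix or '.xml'}"
        part.write_bytes(
            b'<?xml version="1.0"?>\n'
            + etree.tostring(part_root, pretty_print=True)
        )
        paths.append(part)
    return paths
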