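"""Synthetic BLAST datasets and report renderers.

This module is the package's test bed and demo data source: it builds
random-but-reproducible :class:`~blasthits.model.Dataset` objects and can
render any dataset as a valid BLAST XML or classic text report, so that the
parsers, the store and every downstream viewer can be exercised without a
real BLAST run or any download.

Deflines are composed from a word vocabulary plus a ``gi|<n>|`` token and a
bracketed species binomial drawn from the packaged toy taxonomy, so both
taxonomy-annotation routes (gi mapping and name parsing) see realistic
input and the planted truth stays recoverable from the defline itself.
Statistics are internally consistent: bit scores decrease with log10
e-value up to noise, and identity/positive counts fit inside the ungapped
alignment columns.  Rendered alignment rows are synthesised to match the
identity/positive/gap counts exactly, so verbatim-extraction tests see
plausible stanzas.

Sequences are decorative: no attempt is made to simulate real
Karlin-Altschul score statistics.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import InvalidSpec
from .model import HSP, Dataset, SeqEntry
from .taxonomy import TOY_SPECIES

Dist = Union[int, tuple[int, int]]

_DEFAULT_VOCABULARY = [
    "cell adhesion molecule", "down syndrome", "fibronectin type-III",
    "cell", "adhesion", "molecule", "down", "syndrome", "fibronectin",
    "immunoglobulin", "kinase", "receptor", "isoform", "precursor",
    "hypothetical", "protein", "domain", "repeat", "bent", "titin",
    "transmembrane", "uncharacterized", "putative", "homolog", "partial",
]

_DEFAULT_TAXID_POOL: dict[Optional[int], float] = {
    9606: 2.0,    # Homo sapiens
    10090: 1.0,   # Mus musculus
    7227: 2.0,    # Drosophila melanogaster
    6239: 1.0,    # Caenorhabditis elegans
    7955: 1.0,    # Danio rerio
    4932: 1.0,    # Saccharomyces cerevisiae
    3702: 1.0,    # Arabidopsis thaliana
    562: 1.0,     # Escherichia coli
    None: 1.0,    # unannotatable defline (no gi token, no species)
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset; same seed, same bytes out."""

    n_queries: int = 10
    hits_per_query: Dist = (0, 8)
    hsps_per_hit: Dist = (1, 2)
    evalue_log10_range: tuple[float, float] = (-180.0, 1.0)
    bitscore_range: tuple[float, float] = (25.0, 1200.0)
    taxid_pool: dict[Optional[int], float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXID_POOL)
    )
    defline_vocabulary: list[str] = field(
        default_factory=lambda: list(_DEFAULT_VOCABULARY)
    )
    seed: int = 0
    reuse_prob: float = 0.3  # chance a hit reuses an existing defline
    zero_evalue_prob: float = 0.01
    program: str = "BLASTP"

    def validate(self) -> None:
        if self.n_queries < 1:
            raise InvalidSpec("n_queries must be positive")
        for name, dist in (("hits_per_query", self.hits_per_query),
                           ("hsps_per_hit", self.hsps_per_hit)):
            lo, hi = _dist_bounds(dist)
            if hi < lo or hi < 0:
                raise InvalidSpec(f"{name}: empty range {dist!r}")
        if self.evalue_log10_range[1] < self.evalue_log10_range[0]:
            raise InvalidSpec("evalue_log10_range is empty")
        if self.bitscore_range[1] < self.bitscore_range[0]:
            raise InvalidSpec("bitscore_range is empty")
        if not self.taxid_pool or all(w <= 0 for w in self.taxid_pool.values()):
            raise InvalidSpec("taxid_pool is empty")
        for taxid in self.taxid_pool:
            if taxid is not None and taxid not in TOY_SPECIES:
                raise InvalidSpec(
                    f"taxid {taxid} has no species name in the packaged taxonomy"
                )
        if not self.defline_vocabulary:
            raise InvalidSpec("defline_vocabulary is empty")


def _dist_bounds(dist: Dist) -> tuple[int, int]:
    if isinstance(dist, int):
        return dist, dist
    lo, hi = dist
    return int(lo), int(hi)


def _draw(dist: Dist, rng: random.Random) -> int:
    lo, hi = _dist_bounds(dist)
    return lo if lo == hi else rng.randint(lo, hi)


def _quantize(value: float, fmt: str) -> float:
    return float(format(value, fmt))


# ---------------------------------------------------------------------------
# Dataset synthesis
# ---------------------------------------------------------------------------


def planted_taxid(defline: str) -> Optional[int]:
    """Ground-truth taxid of a synthetic defline (from its bracket field)."""
    for taxid, name in TOY_SPECIES.items():
        if f"[{name}]" in defline:
            return taxid
    return None


def synth_dataset(spec: SynthSpec) -> Dataset:
    """Generate a Dataset honouring every Dataset invariant."""
    spec.validate()
    rng = random.Random(spec.seed)
    d = Dataset()

    pool_items = [(t, w) for t, w in spec.taxid_pool.items() if w > 0]
    taxids = [t for t, _ in pool_items]
    weights = [w for _, w in pool_items]

    next_gi = 100001
    vocab = spec.defline_vocabulary

    def new_sequence() -> int:
        nonlocal next_gi
        taxid = rng.choices(taxids, weights=weights)[0]
        phrase = " ".join(rng.choice(vocab) for _ in range(rng.randint(2, 4)))
        if taxid is None:
            defline = f"unnamed product {phrase} clone {len(d.sequences) + 1}"
        else:
            gi = next_gi
            next_gi += rng.randint(1, 9)
            acc = f"XP_{gi % 900000 + 100000}.1"
            defline = f"gi|{gi}|ref|{acc}| {phrase} [{TOY_SPECIES[taxid]}]"
        sid = len(d.sequences)
        d.sequences.append(SeqEntry(defline))
        return sid

    for qi in range(spec.n_queries):
        qname = f"Query_{qi + 1} {rng.choice(vocab)}"
        d.queries.append(qname)
        n_hits = _draw(spec.hits_per_query, rng)
        hit_sids: set[int] = set()
        for _ in range(n_hits):
            can_reuse = len(hit_sids) < len(d.sequences)
            if can_reuse and rng.random() < spec.reuse_prob:
                while True:
                    sid = rng.randrange(len(d.sequences))
                    if sid not in hit_sids:
                        break
            else:
                sid = new_sequence()
            hit_sids.add(sid)
            for _ in range(_draw(spec.hsps_per_hit, rng)):
                d.hsps.append(_synth_hsp(spec, rng, qi, sid))
    d.validate()
    return d


def _synth_hsp(spec: SynthSpec, rng: random.Random, qid: int, sid: int) -> HSP:
    lo, hi = spec.evalue_log10_range
    log10e = rng.uniform(lo, hi)
    if rng.random() < spec.zero_evalue_prob:
        evalue, log10e = 0.0, lo
    else:
        evalue = _quantize(10.0 ** log10e, ".6g")
        if evalue == 0.0:  # underflow below float range
            log10e = lo
    blo, bhi = spec.bitscore_range
    frac = (hi - log10e) / (hi - lo) if hi > lo else 0.5
    bit = blo + frac * (bhi - blo) + rng.gauss(0.0, 0.03 * (bhi - blo) + 1.0)
    bit = _quantize(min(max(bit, blo), bhi), ".1f")
    raw = int(round(bit * 2.1 + 5))

    align_len = rng.randint(40, 300)
    gaps = 0 if rng.random() < 0.6 else rng.randint(1, max(1, align_len // 10))
    max_match = align_len - gaps
    identities = rng.randint(max(1, int(0.25 * max_match)), max_match)
    positives = rng.randint(identities, max_match)
    q_start = rng.randint(1, 400)
    s_start = rng.randint(1, 600)
    # gaps sit in the subject rows, so the query span covers align_len columns
    return HSP(
        query_id=qid, seq_id=sid,
        evalue=evalue, bit_score=bit, raw_score=raw,
        identity_pct=100.0 * identities / align_len,
        positive_pct=100.0 * positives / align_len,
        gaps=gaps, align_len=align_len,
        q_start=q_start, q_end=q_start + align_len - 1,
        s_start=s_start, s_end=s_start + (align_len - gaps) - 1,
        q_frame=0, s_frame=0,
    )


def write_gi_mapping(d: Dataset, path) -> Path:
    """gi -> taxid mapping for every synthetic defline with a planted species."""
    from .taxonomy import extract_gi

    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for seq in d.sequences:
            gi = extract_gi(seq.defline)
            taxid = planted_taxid(seq.defline)
            if gi is not None and taxid is not None:
                fh.write(f"{gi}\t{taxid}\n")
    return path


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def format_evalue(v: float) -> str:
    return "0.0" if v == 0 else format(v, ".6g")


def _hsp_counts(h: HSP) -> tuple[int, int, int]:
    """Integer (identities, positives, gaps) back from the percentages."""
    identities = int(round(h.identity_pct * h.align_len / 100.0))
    positives = int(round(h.positive_pct * h.align_len / 100.0))
    avail = max(1, h.align_len - h.gaps)
    identities = min(max(identities, 0), avail)
    positives = min(max(positives, 0), avail)
    return identities, positives, h.gaps


def _synth_alignment(h: HSP, key: str) -> tuple[str, str, str]:
    """Deterministic (qseq, midline, hseq) matching the HSP's counts."""
    rng = random.Random(zlib.crc32(key.encode("utf-8")))
    L = h.align_len
    q_gaps = max(0, L - (h.q_end - h.q_start + 1))
    s_gaps = max(0, L - (h.s_end - h.s_start + 1))
    positions = list(range(L))
    rng.shuffle(positions)
    q_gap_set = set(positions[:q_gaps])
    s_gap_set = set(positions[q_gaps:q_gaps + s_gaps])
    free = [p for p in positions[q_gaps + s_gaps:]]
    identities, positives, _ = _hsp_counts(h)
    identities = min(identities, len(free))
    positives = min(max(positives, identities), len(free))
    ident_set = set(free[:identities])
    pos_only = set(free[identities:positives])

    q_chars, m_chars, s_chars = [], [], []
    for p in range(L):
        qc = "-" if p in q_gap_set else _AA[rng.randrange(len(_AA))]
        if p in s_gap_set:
            sc = "-"
        elif p in ident_set:
            sc = qc
        else:
            sc = _AA[(_AA.index(qc) + rng.randint(1, len(_AA) - 1)) % len(_AA)] \
                if qc != "-" else _AA[rng.randrange(len(_AA))]
        if p in ident_set:
            mc = qc
        elif p in pos_only:
            mc = "+"
        else:
            mc = " "
        q_chars.append(qc)
        m_chars.append(mc)
        s_chars.append(sc)
    return "".join(q_chars), "".join(m_chars), "".join(s_chars)


def _pct(n: int, total: int) -> int:
    return int(round(100.0 * n / total)) if total else 0


def render_text(d: Dataset, program: str = "BLASTP", version: str = "2.2.26+") -> str:
    """Render a classic pairwise text report."""
    out: list[str] = [f"{program} {version}", "", ""]
    out += ["Reference: synthetic report rendered for testing", "", ""]
    out += ["Database: synthetic",
            f"           {len(d.sequences)} sequences; "
            f"{sum(h.align_len for h in d.hsps) or 1} total letters", ""]

    by_query: dict[int, list[int]] = {q: [] for q in range(len(d.queries))}
    for i, h in enumerate(d.hsps):
        by_query[h.query_id].append(i)

    for qid, qname in enumerate(d.queries):
        hsp_ids = by_query[qid]
        qlen = max((d.hsps[i].q_end for i in hsp_ids), default=100)
        out += ["", "", f"Query= {qname}", "", f"Length={qlen}"]
        if not hsp_ids:
            out += ["", "", "***** No hits found *****", ""]
            continue
        # group by sequence, preserving first-appearance order
        order: list[int] = []
        per_seq: dict[int, list[int]] = {}
        for i in hsp_ids:
            sid = d.hsps[i].seq_id
            if sid not in per_seq:
                per_seq[sid] = []
                order.append(sid)
            per_seq[sid].append(i)
        for sid in order:
            defline = d.sequences[sid].defline
            slen = max(d.hsps[i].s_end for i in per_seq[sid])
            out += ["", f">{defline}", f"Length={slen}"]
            for i in per_seq[sid]:
                out += _render_text_hsp(d, i, program)
    out += ["", "", "Lambda      K        H", "   0.318    0.134    0.401", "",
            "  Database: synthetic", ""]
    return "\n".join(out)


def _render_text_hsp(d: Dataset, hsp_index: int, program: str) -> list[str]:
    h = d.hsps[hsp_index]
    identities, positives, gaps = _hsp_counts(h)
    L = h.align_len
    lines = ["", f" Score = {h.bit_score:.1f} bits ({h.raw_score}),  "
                 f"Expect = {format_evalue(h.evalue)}"]
    stat = f" Identities = {identities}/{L} ({_pct(identities, L)}%)"
    if program != "BLASTN":
        stat += f", Positives = {positives}/{L} ({_pct(positives, L)}%)"
    stat += f", Gaps = {gaps}/{L} ({_pct(gaps, L)}%)"
    lines.append(stat)
    if program == "BLASTN" and (h.q_frame or h.s_frame):
        qs = "Plus" if h.q_frame >= 0 else "Minus"
        ss = "Plus" if h.s_frame >= 0 else "Minus"
        lines.append(f" Strand={qs}/{ss}")
    elif program == "BLASTX" and h.q_frame:
        lines.append(f" Frame = {h.q_frame:+d}")
    elif program == "TBLASTN" and h.s_frame:
        lines.append(f" Frame = {h.s_frame:+d}")
    elif program == "TBLASTX" and (h.q_frame or h.s_frame):
        lines.append(f" Frame = {h.q_frame:+d} / {h.s_frame:+d}")
    lines.append("")

    key = f"{d.queries[h.query_id]}|{d.sequences[h.seq_id].defline}|{hsp_index}|" \
          f"{h.q_start}:{h.s_start}:{h.bit_score}"
    qseq, midline, hseq = _synth_alignment(h, key)
    q_pos = h.q_start if h.q_frame >= 0 else h.q_end
    s_pos = h.s_start if h.s_frame >= 0 else h.s_end
    q_step = 1 if h.q_frame >= 0 else -1
    s_step = 1 if h.s_frame >= 0 else -1
    width = 10
    q_consumed = s_consumed = False
    for off in range(0, len(qseq), 60):
        q_chunk, m_chunk, s_chunk = qseq[off:off + 60], midline[off:off + 60], hseq[off:off + 60]
        nq = sum(c != "-" for c in q_chunk)
        ns = sum(c != "-" for c in s_chunk)
        # a row consuming no residues repeats the last consumed coordinate,
        # so the parser's min/max over printed coordinates stays exact
        if nq:
            q_from_here, q_end_here = q_pos, q_pos + q_step * (nq - 1)
        else:
            q_from_here = q_end_here = (q_pos - q_step) if q_consumed else q_pos
        if ns:
            s_from_here, s_end_here = s_pos, s_pos + s_step * (ns - 1)
        else:
            s_from_here = s_end_here = (s_pos - s_step) if s_consumed else s_pos
        lines.append(f"Query  {q_from_here:<{width}}{q_chunk}  {q_end_here}")
        lines.append(f"       {'':<{width}}{m_chunk}")
        lines.append(f"Sbjct  {s_from_here:<{width}}{s_chunk}  {s_end_here}")
        lines.append("")
        if nq:
            q_pos = q_end_here + q_step
            q_consumed = True
        if ns:
            s_pos = s_end_here + s_step
            s_consumed = True
    return lines


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _split_defline(defline: str, n: int) -> tuple[str, str]:
    parts = defline.split(" ", 1)
    if len(parts) == 2 and "|" in parts[0] and not parts[0].startswith(("gnl|BL_ORD_ID|", "lcl|")):
        return parts[0], parts[1]
    return f"gnl|BL_ORD_ID|{n}", defline


def render_xml(d: Dataset, program: str = "blastp", version: str = "BLASTP 2.2.26+") -> str:
    """Render NCBI BLAST XML (one Iteration per query)."""
    w: list[str] = ['<?xml version="1.0"?>',
                    '<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" '
                    '"http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">',
                    "<BlastOutput>",
                    f"  <BlastOutput_program>{program}</BlastOutput_program>",
                    f"  <BlastOutput_version>{version}</BlastOutput_version>",
                    "  <BlastOutput_db>synthetic</BlastOutput_db>",
                    "  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>",
                    "  <BlastOutput_param>",
                    "    <Parameters>",
                    "      <Parameters_matrix>BLOSUM62</Parameters_matrix>",
                    "      <Parameters_expect>10</Parameters_expect>",
                    "      <Parameters_gap-open>11</Parameters_gap-open>",
                    "      <Parameters_gap-extend>1</Parameters_gap-extend>",
                    "      <Parameters_filter>F</Parameters_filter>",
                    "    </Parameters>",
                    "  </BlastOutput_param>",
                    "  <BlastOutput_iterations>"]
    by_query: dict[int, list[int]] = {q: [] for q in range(len(d.queries))}
    for i, h in enumerate(d.hsps):
        by_query[h.query_id].append(i)

    for qid, qname in enumerate(d.queries):
        hsp_ids = by_query[qid]
        qlen = max((d.hsps[i].q_end for i in hsp_ids), default=100)
        w += ["    <Iteration>",
              f"      <Iteration_iter-num>{qid + 1}</Iteration_iter-num>",
              f"      <Iteration_query-ID>Query_{qid + 1}</Iteration_query-ID>",
              f"      <Iteration_query-def>{_xml_escape(qname)}</Iteration_query-def>",
              f"      <Iteration_query-len>{qlen}</Iteration_query-len>",
              "      <Iteration_hits>"]
        order: list[int] = []
        per_seq: dict[int, list[int]] = {}
        for i in hsp_ids:
            sid = d.hsps[i].seq_id
            if sid not in per_seq:
                per_seq[sid] = []
                order.append(sid)
            per_seq[sid].append(i)
        for hit_num, sid in enumerate(order, start=1):
            defline = d.sequences[sid].defline
            hit_id, hit_def = _split_defline(defline, sid)
            slen = max(d.hsps[i].s_end for i in per_seq[sid])
            w += ["        <Hit>",
                  f"          <Hit_num>{hit_num}</Hit_num>",
                  f"          <Hit_id>{_xml_escape(hit_id)}</Hit_id>",
                  f"          <Hit_def>{_xml_escape(hit_def)}</Hit_def>",
                  f"          <Hit_accession>{sid}</Hit_accession>",
                  f"          <Hit_len>{slen}</Hit_len>",
                  "          <Hit_hsps>"]
            for hsp_num, i in enumerate(per_seq[sid], start=1):
                h = d.hsps[i]
                identities, positives, _g = _hsp_counts(h)
                key = f"{qname}|{defline}|{i}|{h.q_start}:{h.s_start}:{h.bit_score}"
                qseq, midline, hseq = _synth_alignment(h, key)
                s_from, s_to = h.s_start, h.s_end
                if h.s_frame < 0:
                    s_from, s_to = s_to, s_from
                q_from, q_to = h.q_start, h.q_end
                if h.q_frame < 0:
                    q_from, q_to = q_to, q_from
                w += ["            <Hsp>",
                      f"              <Hsp_num>{hsp_num}</Hsp_num>",
                      f"              <Hsp_bit-score>{h.bit_score:.1f}</Hsp_bit-score>",
                      f"              <Hsp_score>{h.raw_score}</Hsp_score>",
                      f"              <Hsp_evalue>{format_evalue(h.evalue)}</Hsp_evalue>",
                      f"              <Hsp_query-from>{q_from}</Hsp_query-from>",
                      f"              <Hsp_query-to>{q_to}</Hsp_query-to>",
                      f"              <Hsp_hit-from>{s_from}</Hsp_hit-from>",
                      f"              <Hsp_hit-to>{s_to}</Hsp_hit-to>",
                      f"              <Hsp_query-frame>{h.q_frame}</Hsp_query-frame>",
                      f"              <Hsp_hit-frame>{h.s_frame}</Hsp_hit-frame>",
                      f"              <Hsp_identity>{identities}</Hsp_identity>",
                      f"              <Hsp_positive>{positives}</Hsp_positive>",
                      f"              <Hsp_gaps>{h.gaps}</Hsp_gaps>",
                      f"              <Hsp_align-len>{h.align_len}</Hsp_align-len>",
                      f"              <Hsp_qseq>{qseq}</Hsp_qseq>",
                      f"              <Hsp_hseq>{hseq}</Hsp_hseq>",
                      f"              <Hsp_midline>{_xml_escape(midline)}</Hsp_midline>",
                      "            </Hsp>"]
            w += ["          </Hit_hsps>", "        </Hit>"]
        w += ["      </Iteration_hits>", "    </Iteration>"]
    w += ["  </BlastOutput_iterations>", "</BlastOutput>", ""]
    return "\n".join(w)


def render_report(d: Dataset, dialect: str, path) -> Path:
    """Write ``d`` as a BLAST report; the file parses back canonically equal."""
    path = Path(path)
    if dialect == "xml":
        content = render_xml(d)
    elif dialect == "text":
        content = render_text(d)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text(content, encoding="utf-8")
    return path
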