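"""NCBI taxonomy: loading, hit annotation and expand/collapse frontiers.

Only scientific names are kept when loading a taxdump, which keeps the tree
small and makes name-based defline annotation unambiguous.  Two annotation
routes are supported, mirroring the two ways a hit's organism can be known:

* ``annotate_by_gi`` — a two-column ``gi<TAB>taxid`` mapping file, with the
  gi number extracted from the defline's ``gi|<digits>|`` token;
* ``annotate_by_name`` — scanning the defline for scientific names, trying
  bracketed organism fields first, then two-word binomials, then single-word
  (genus) names; the longest match wins and ties between distinct taxa leave
  the sequence unassigned.

An :class:`ExpansionState` records which tree nodes are expanded; the
*frontier* it induces (deepest nodes all of whose strict ancestors are
expanded) is what a taxonomy matrix axis displays, and
:func:`visible_ancestor` maps any taxon to its frontier representative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import FormatError, UnknownTaxid
from .model import Dataset

ROOT_TAXID = 1


@dataclass
class TaxNode:
    parent: int
    name: str
    rank: str = "no rank"


class TaxTree:
    """Parent-linked taxonomy with one scientific name per node."""

    def __init__(self, nodes: dict[int, TaxNode]):
        self.nodes = nodes
        self.root = ROOT_TAXID
        self._children: Optional[dict[int, list[int]]] = None
        self._name_index: Optional[dict[str, int]] = None

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid].parent

    def children(self, taxid: int) -> list[int]:
        if self._children is None:
            ch: dict[int, list[int]] = {t: [] for t in self.nodes}
            for t, node in self.nodes.items():
                if t != self.root:
                    ch[node.parent].append(t)
            for kids in ch.values():
                kids.sort(key=lambda t: self.nodes[t].name.casefold())
            self._children = ch
        return self._children[taxid]

    def path_from_root(self, taxid: int) -> list[int]:
        if taxid not in self.nodes:
            raise UnknownTaxid(f"taxid {taxid} not in tree")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent)
        path.reverse()
        return path

    @property
    def name_index(self) -> dict[str, int]:
        """Casefolded scientific name -> taxid; ambiguous names map to -1."""
        if self._name_index is None:
            index: dict[str, int] = {}
            for taxid, node in self.nodes.items():
                key = node.name.casefold()
                if key in index and index[key] != taxid:
                    index[key] = -1
                else:
                    index[key] = taxid
            self._name_index = index
        return self._name_index


def _dmp_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield lineno, [f.strip() for f in line.split("\t|\t")]


def load_taxdump(nodes_path, names_path) -> TaxTree:
    """Load NCBI taxdump nodes.dmp/names.dmp; scientific names only.

    Nodes lacking a ``scientific name`` row fall back to ``taxid:<n>``.
    Cycles (a non-root node that is its own ancestor) raise FormatError.
    """
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    parents: dict[int, tuple[int, str]] = {}
    for lineno, fields in _dmp_rows(nodes_path):
        if len(fields) < 2:
            raise FormatError(f"{nodes_path}:{lineno}: expected taxid|parent|rank")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{nodes_path}:{lineno}: non-integer taxid") from exc
        rank = fields[2] if len(fields) > 2 else "no rank"
        parents[taxid] = (parent, rank)

    names: dict[int, str] = {}
    for lineno, fields in _dmp_rows(names_path):
        if len(fields) < 4:
            continue  # tolerate short rows (class column absent)
        taxid_s, name_txt, _unique, name_class = fields[0], fields[1], fields[2], fields[3]
        if name_class != "scientific name":
            continue
        try:
            names[int(taxid_s)] = name_txt
        except ValueError as exc:
            raise FormatError(f"{names_path}:{lineno}: non-integer taxid") from exc

    nodes: dict[int, TaxNode] = {}
    for taxid, (parent, rank) in parents.items():
        if taxid != ROOT_TAXID and parent == taxid:
            raise FormatError(f"{nodes_path}: node {taxid} is its own parent (cycle)")
        if parent not in parents:
            raise FormatError(f"{nodes_path}: node {taxid} has unknown parent {parent}")
        nodes[taxid] = TaxNode(parent=parent, name=names.get(taxid, f"taxid:{taxid}"), rank=rank)
    if ROOT_TAXID not in nodes:
        raise FormatError(f"{nodes_path}: no root node (taxid {ROOT_TAXID})")

    # reachability doubles as cycle detection
    for taxid in nodes:
        seen = set()
        cur = taxid
        while cur != ROOT_TAXID:
            if cur in seen:
                raise FormatError(f"{nodes_path}: cycle through taxid {cur}")
            seen.add(cur)
            cur = nodes[cur].parent
    return TaxTree(nodes)


# ---------------------------------------------------------------------------
# Expansion state / frontier
# ---------------------------------------------------------------------------


@dataclass
class ExpansionState:
    """Set of expanded taxids; the root is always visible."""

    expanded: set[int] = field(default_factory=set)

    def expand(self, taxid: int) -> None:
        self.expanded.add(taxid)

    def collapse(self, taxid: int) -> None:
        self.expanded.discard(taxid)


def visible_ancestor(taxid: int, tree: TaxTree, state: ExpansionState) -> int:
    """Deepest ancestor (or self) whose strict ancestors are all expanded."""
    path = tree.path_from_root(taxid)
    current = path[0]
    for nxt in path[1:]:
        if current not in state.expanded:
            break
        current = nxt
    return current


def frontier(tree: TaxTree, state: ExpansionState) -> list[int]:
    """All visible nodes in depth-first order (root first).

    A node is visible when every strict ancestor is expanded; expanded
    internal nodes stay visible alongside their children, since a hit
    annotated exactly at such a node still needs a row of its own.
    """
    out: list[int] = []

    def walk(taxid: int) -> None:
        out.append(taxid)
        if taxid in state.expanded:
            for child in tree.children(taxid):
                walk(child)

    walk(tree.root)
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_GI_TOKEN = re.compile(r"gi\|(\d+)\|")
_BRACKET = re.compile(r"\[([^\[\]]+)\]")
_WORD = re.compile(r"[A-Za-z][A-Za-z.'-]*")


@dataclass
class AnnotationReport:
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    skipped_existing: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.ambiguous + self.skipped_existing


def extract_gi(defline: str) -> Optional[int]:
    m = _GI_TOKEN.search(defline)
    return int(m.group(1)) if m else None


def load_gi_mapping(path) -> dict[int, int]:
    """Two-column ``gi<TAB>taxid`` file (extra columns ignored)."""
    mapping: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected gi<TAB>taxid")
            try:
                mapping[int(fields[0])] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
    return mapping


def annotate_by_gi(
    d: Dataset,
    mapping_path,
    tree: Optional[TaxTree] = None,
    overwrite: bool = False,
) -> AnnotationReport:
    """Assign TAXIDs from the defline's gi number via a mapping file.

    A gi that maps to a taxid absent from ``tree`` (when a tree is given)
    counts as unassigned.  Existing taxids are kept unless ``overwrite``.
    """
    mapping = load_gi_mapping(mapping_path)
    report = AnnotationReport()
    for seq in d.sequences:
        if seq.taxid is not None and not overwrite:
            report.skipped_existing += 1
            continue
        gi = extract_gi(seq.defline)
        taxid = mapping.get(gi) if gi is not None else None
        if taxid is not None and (tree is None or taxid in tree):
            seq.taxid = taxid
            report.assigned += 1
        else:
            report.unassigned += 1
    return report


def _name_matches(text: str, index: dict[str, int]) -> list[tuple[int, int]]:
    """(match length, taxid) for every scientific name found in ``text``.

    Tries two-word windows (binomials) and single words; matches are exact
    against the casefolded name index.
    """
    words = _WORD.findall(text)
    found: list[tuple[int, int]] = []
    for i, word in enumerate(words):
        if i + 1 < len(words):
            bigram = f"{word} {words[i + 1]}"
            taxid = index.get(bigram.casefold())
            if taxid is not None and taxid != -1:
                found.append((len(bigram), taxid))
        taxid = index.get(word.casefold())
        if taxid is not None and taxid != -1:
            found.append((len(word), taxid))
    return found


def resolve_defline_taxid(defline: str, tree: TaxTree) -> tuple[Optional[int], bool]:
    """(taxid or None, ambiguous?) for one defline.

    Precedence: bracketed organism fields, then binomial/genus scan of the
    whole defline; within a tier the longest match wins and a length tie
    between distinct taxids is ambiguous.
    """
    index = tree.name_index
    candidates: list[tuple[int, int]] = []
    for m in _BRACKET.finditer(defline):
        name = m.group(1).strip()
        taxid = index.get(name.casefold())
        if taxid is not None and taxid != -1:
            candidates.append((len(name), taxid))
        else:
            candidates.extend(_name_matches(name, index))
    if not candidates:
        candidates = _name_matches(defline, index)
    if not candidates:
        return None, False
    best_len = max(length for length, _ in candidates)
    best = {taxid for length, taxid in candidates if length == best_len}
    if len(best) > 1:
        return None, True
    return best.pop(), False


def annotate_by_name(
    d: Dataset, tree: TaxTree, overwrite: bool = False
) -> AnnotationReport:
    """Assign TAXIDs by scanning deflines for scientific names."""
    report = AnnotationReport()
    for seq in d.sequences:
        if seq.taxid is not None and not overwrite:
            report.skipped_existing += 1
            continue
        taxid, ambiguous = resolve_defline_taxid(seq.defline, tree)
        if taxid is not None:
            seq.taxid = taxid
            report.assigned += 1
        elif ambiguous:
            report.ambiguous += 1
        else:
            report.unassigned += 1
    return report


# ---------------------------------------------------------------------------
# Packaged toy taxonomy (generated, not downloaded)
# ---------------------------------------------------------------------------

#: (taxid, parent, rank, scientific name) — a ~50-node slice of the NCBI
#: taxonomy covering the metazoan path (Deuterostomia, Nematoda, sponges,
#: placozoans ...) plus fungal, plant and bacterial outgroups.
TOY_TAXA: list[tuple[int, int, str, str]] = [
    (1, 1, "no rank", "root"),
    (131567, 1, "no rank", "cellular organisms"),
    (2759, 131567, "superkingdom", "Eukaryota"),
    (33154, 2759, "no rank", "Opisthokonta"),
    (33208, 33154, "kingdom", "Metazoa"),
    (6072, 33208, "no rank", "Eumetazoa"),
    (33213, 6072, "no rank", "Bilateria"),
    (33511, 33213, "no rank", "Deuterostomia"),
    (7711, 33511, "phylum", "Chordata"),
    (89593, 7711, "subphylum", "Craniata"),
    (7742, 89593, "no rank", "Vertebrata"),
    (117571, 7742, "no rank", "Euteleostomi"),
    (40674, 117571, "class", "Mammalia"),
    (9443, 40674, "order", "Primates"),
    (9604, 9443, "family", "Hominidae"),
    (9605, 9604, "genus", "Homo"),
    (9606, 9605, "species", "Homo sapiens"),
    (9989, 40674, "order", "Rodentia"),
    (10088, 9989, "genus", "Mus"),
    (10090, 10088, "species", "Mus musculus"),
    (7898, 117571, "class", "Actinopterygii"),
    (7954, 7898, "genus", "Danio"),
    (7955, 7954, "species", "Danio rerio"),
    (33317, 33213, "no rank", "Protostomia"),
    (1206794, 33317, "no rank", "Ecdysozoa"),
    (6231, 1206794, "phylum", "Nematoda"),
    (6237, 6231, "genus", "Caenorhabditis"),
    (6239, 6237, "species", "Caenorhabditis elegans"),
    (6656, 1206794, "phylum", "Arthropoda"),
    (50557, 6656, "class", "Insecta"),
    (7147, 50557, "order", "Diptera"),
    (7215, 7147, "genus", "Drosophila"),
    (7227, 7215, "species", "Drosophila melanogaster"),
    (6040, 33208, "phylum", "Porifera"),
    (400681, 6040, "genus", "Amphimedon"),
    (400682, 400681, "species", "Amphimedon queenslandica"),
    (10226, 33208, "phylum", "Placozoa"),
    (10227, 10226, "genus", "Trichoplax"),
    (10228, 10227, "species", "Trichoplax adhaerens"),
    (6073, 6072, "phylum", "Cnidaria"),
    (45350, 6073, "genus", "Nematostella"),
    (45351, 45350, "species", "Nematostella vectensis"),
    (192875, 33154, "genus", "Capsaspora"),
    (595528, 192875, "species", "Capsaspora owczarzaki"),
    (4751, 33154, "kingdom", "Fungi"),
    (4890, 4751, "phylum", "Ascomycota"),
    (4930, 4890, "genus", "Saccharomyces"),
    (4932, 4930, "species", "Saccharomyces cerevisiae"),
    (33090, 2759, "kingdom", "Viridiplantae"),
    (3701, 33090, "genus", "Arabidopsis"),
    (3702, 3701, "species", "Arabidopsis thaliana"),
    (2, 131567, "superkingdom", "Bacteria"),
    (1224, 2, "phylum", "Proteobacteria"),
    (561, 1224, "genus", "Escherichia"),
    (562, 561, "species", "Escherichia coli"),
]

#: Species-level taxids with binomial names, usable as a generator pool.
TOY_SPECIES: dict[int, str] = {
    taxid: name for taxid, _p, rank, name in TOY_TAXA if rank == "species"
}

#: A few non-scientific name rows, to exercise the scientific-name filter.
_TOY_EXTRA_NAMES = [
    (9606, "man", "", "genbank common name"),
    (9606, "Homo sapiens Linnaeus, 1758", "", "authority"),
    (10090, "house mouse", "", "genbank common name"),
    (7227, "fruit fly", "", "genbank common name"),
    (562, "Bacillus coli", "", "synonym"),
]


def write_toy_taxdump(dest_dir) -> tuple[Path, Path]:
    """Write nodes.dmp/names.dmp for the packaged toy taxonomy slice."""
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    nodes_path, names_path = dest / "nodes.dmp", dest / "names.dmp"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid, parent, rank, _name in TOY_TAXA:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid, _parent, _rank, name in TOY_TAXA:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
        for taxid, name, unique, klass in _TOY_EXTRA_NAMES:
            fh.write(f"{taxid}\t|\t{name}\t|\t{unique}\t|\t{klass}\t|\n")
    return nodes_path, names_path


def load_toy_tree() -> TaxTree:
    """The packaged toy taxonomy as a TaxTree, without touching disk."""
    nodes = {
        taxid: TaxNode(parent=parent, name=name, rank=rank)
        for taxid, parent, rank, name in TOY_TAXA
    }
    return TaxTree(nodes)
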