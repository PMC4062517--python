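"""The matrix viewer engine: cross-tabulate HSPs along two axes.

An axis bins HSPs either by intervals of a numeric attribute (half-open
``[low, high)`` bins, e-values binned on the log10 scale with a dedicated
bin for BLAST's printed ``0.0``), by category (query or hit sequence), or
by taxonomy frontier (the visible nodes of an expand/collapse state, plus
an ``unassigned`` row for hits without a TAXID).  Every HSP lands in
exactly one (row, column) cell, so cell counts always sum to the HSP total
regardless of the axis pair.

Cells carry a statistic — HSP count by default (distinct query-sequence
pairs or distinct queries as alternatives), or mean/min/max of any numeric
HSP attribute — which can be min-max normalised for heat-map display,
sorted on, and thresholded to "grab" a :class:`~blasthits.selection.Selection`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

from .errors import (BadEdges, EmptyMatrix, NoSuchCell, UnknownAttribute)
from .model import NUMERIC_ATTRIBUTES, Dataset
from .selection import Selection
from .taxonomy import ExpansionState, TaxTree, frontier, visible_ancestor

UNASSIGNED_LABEL = "unassigned"
ZERO_EVALUE_LABEL = "0"


def _fmt_edge(x: float) -> str:
    return format(x, "g")


@dataclass
class Axis:
    """One matrix dimension; ``assign`` maps an HSP index to a label or None."""

    kind: str                      # interval | category | taxonomy
    labels: list[str]
    assign: Callable[[Dataset, int], Optional[str]]
    attribute: Optional[str] = None
    edges: Optional[list[float]] = None


def build_interval_axis(
    attribute: str,
    edges: Sequence[float],
    include_underflow: bool = True,
    include_overflow: bool = True,
) -> Axis:
    """Interval axis over a numeric HSP attribute.

    Bins are half-open ``[low, high)``.  For ``evalue`` the edges are log10
    exponents (an axis "between e-10 and e-5" is ``edges=[-10, -5]``) and the
    binned value is log10(evalue); e-value exactly 0 goes to a dedicated
    ``0`` bin that precedes underflow.
    """
    if attribute not in NUMERIC_ATTRIBUTES:
        raise UnknownAttribute(f"no such HSP attribute: {attribute!r}")
    edges = [float(e) for e in edges]
    if not edges:
        raise BadEdges("at least one bin edge required")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise BadEdges(f"edges must be strictly increasing: {edges}")

    is_evalue = attribute == "evalue"
    labels: list[str] = []
    if is_evalue:
        labels.append(ZERO_EVALUE_LABEL)
        shown = [f"1e{_fmt_edge(e)}" for e in edges]
    else:
        shown = [_fmt_edge(e) for e in edges]
    underflow_label = f"(-inf,{shown[0]})"
    overflow_label = f"[{shown[-1]},inf)"
    mid_labels = [f"[{a},{b})" for a, b in zip(shown, shown[1:])]
    if include_underflow:
        labels.append(underflow_label)
    labels += mid_labels
    if include_overflow:
        labels.append(overflow_label)

    def assign(d: Dataset, i: int) -> Optional[str]:
        value = getattr(d.hsps[i], attribute)
        if is_evalue:
            if value == 0:
                return ZERO_EVALUE_LABEL
            value = math.log10(value)
        if value < edges[0]:
            return underflow_label if include_underflow else None
        for a, b, lab in zip(edges, edges[1:], mid_labels):
            if a <= value < b:
                return lab
        return overflow_label if include_overflow else None

    return Axis(kind="interval", labels=labels, assign=assign,
                attribute=attribute, edges=edges)


def build_category_axis(attribute: str, d: Dataset) -> Axis:
    """Categorical axis over query names or hit deflines."""
    if attribute == "query":
        labels = list(d.queries)

        def assign(ds: Dataset, i: int) -> str:
            return ds.queries[ds.hsps[i].query_id]
    elif attribute == "sequence":
        labels = [s.defline for s in d.sequences]

        def assign(ds: Dataset, i: int) -> str:
            return ds.sequences[ds.hsps[i].seq_id].defline
    else:
        raise UnknownAttribute(f"category axis needs 'query' or 'sequence', got {attribute!r}")
    return Axis(kind="category", labels=labels, assign=assign, attribute=attribute)


def build_taxonomy_axis(tree: TaxTree, state: Optional[ExpansionState] = None) -> Axis:
    """Taxonomy frontier axis; rows are the visible nodes in tree order."""
    state = state or ExpansionState()
    nodes = frontier(tree, state)
    labels = [tree.name(t) for t in nodes] + [UNASSIGNED_LABEL]

    def assign(ds: Dataset, i: int) -> str:
        taxid = ds.sequences[ds.hsps[i].seq_id].taxid
        if taxid is None or taxid not in tree:
            return UNASSIGNED_LABEL
        return tree.name(visible_ancestor(taxid, tree, state))

    return Axis(kind="taxonomy", labels=labels, assign=assign)


# ---------------------------------------------------------------------------
# Matrix
# ---------------------------------------------------------------------------

Statistic = tuple[str, Optional[str]]  # ("count", None) or ("mean", "evalue") ...


@dataclass
class Matrix:
    row_axis: Axis
    col_axis: Axis
    row_labels: list[str]
    col_labels: list[str]
    cells: dict[tuple[int, int], list[int]]
    statistic: Statistic
    values: dict[tuple[int, int], float]
    dataset: Dataset
    n_unassigned: int = 0   # hits in the taxonomy 'unassigned' row/col
    n_dropped: int = 0      # hits outside a flagged-off underflow/overflow bin

    def total_count(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def row_total(self, ri: int) -> int:
        return sum(len(v) for (r, _c), v in self.cells.items() if r == ri)

    def col_total(self, ci: int) -> int:
        return sum(len(v) for (_r, c), v in self.cells.items() if c == ci)


def _stat_value(d: Dataset, members: list[int], statistic: Statistic) -> float:
    kind, attr = statistic
    if kind == "count":
        if attr in (None, "hsp"):
            return float(len(members))
        if attr == "pair":
            return float(len({(d.hsps[i].query_id, d.hsps[i].seq_id) for i in members}))
        if attr == "query":
            return float(len({d.hsps[i].query_id for i in members}))
        raise UnknownAttribute(f"unknown count unit {attr!r}")
    if attr not in NUMERIC_ATTRIBUTES:
        raise UnknownAttribute(f"no such HSP attribute: {attr!r}")
    values = [getattr(d.hsps[i], attr) for i in members]
    if kind == "mean":
        return sum(values) / len(values)
    if kind == "min":
        return min(values)
    if kind == "max":
        return max(values)
    raise UnknownAttribute(f"unknown statistic {kind!r}")


def cross_tabulate(
    d: Dataset,
    rows: Axis,
    cols: Axis,
    statistic: Statistic = ("count", None),
) -> Matrix:
    """Assign every HSP to one (row, col) cell and compute cell statistics.

    HSPs falling outside a flagged-off underflow/overflow bin are dropped
    and counted in ``Matrix.n_dropped`` (with default axis flags nothing is
    ever dropped); taxonomy axes route hits without a TAXID to the
    ``unassigned`` row, counted in ``Matrix.n_unassigned``.
    """
    row_index = {lab: k for k, lab in enumerate(rows.labels)}
    col_index = {lab: k for k, lab in enumerate(cols.labels)}
    cells: dict[tuple[int, int], list[int]] = {}
    n_unassigned = n_dropped = 0
    for i in range(len(d.hsps)):
        r_lab = rows.assign(d, i)
        c_lab = cols.assign(d, i)
        if r_lab is None or c_lab is None:
            n_dropped += 1
            continue
        if UNASSIGNED_LABEL in (r_lab, c_lab):
            n_unassigned += 1
        cells.setdefault((row_index[r_lab], col_index[c_lab]), []).append(i)
    values = {rc: _stat_value(d, members, statistic)
              for rc, members in cells.items()}
    return Matrix(
        row_axis=rows, col_axis=cols,
        row_labels=list(rows.labels), col_labels=list(cols.labels),
        cells=cells, statistic=statistic, values=values, dataset=d,
        n_unassigned=n_unassigned, n_dropped=n_dropped,
    )


def heatmap_normalize(m: Matrix) -> Matrix:
    """Min-max normalise cell values into [0, 1] over non-empty cells.

    E-value statistics are normalised on the log10 scale (a printed 0.0 is
    clamped to 1e-300 first); a constant matrix maps everything to 0.5.
    """
    if not m.values:
        raise EmptyMatrix("no non-empty cells to normalise")
    values = dict(m.values)
    if m.statistic[1] == "evalue" and m.statistic[0] in ("mean", "min", "max"):
        values = {rc: math.log10(max(v, 1e-300)) for rc, v in values.items()}
    vmin, vmax = min(values.values()), max(values.values())
    if vmax == vmin:
        norm = {rc: 0.5 for rc in values}
    else:
        norm = {rc: (v - vmin) / (vmax - vmin) for rc, v in values.items()}
    return Matrix(
        row_axis=m.row_axis, col_axis=m.col_axis,
        row_labels=list(m.row_labels), col_labels=list(m.col_labels),
        cells=m.cells, statistic=m.statistic, values=norm, dataset=m.dataset,
        n_unassigned=m.n_unassigned, n_dropped=m.n_dropped,
    )


def sort_matrix(m: Matrix, by: str = "row_total", direction: str = "desc",
                which: str = "rows") -> Matrix:
    """Stable sort of rows or columns; ties break by label ascending.

    ``by``: ``label`` or ``total`` (marginal HSP count of the row/column);
    ``which`` selects rows or cols; legacy ``row_total``/``col_total``
    select both at once.
    """
    if by == "row_total":
        by, which = "total", "rows"
    elif by == "col_total":
        by, which = "total", "cols"
    reverse = direction == "desc"
    if which == "rows":
        n = len(m.row_labels)
        totals = [m.row_total(k) for k in range(n)]
        labels = m.row_labels
    else:
        n = len(m.col_labels)
        totals = [m.col_total(k) for k in range(n)]
        labels = m.col_labels
    if by == "label":
        order = sorted(range(n), key=lambda k: labels[k], reverse=reverse)
    elif by == "total":
        order = sorted(range(n), key=lambda k: ((-totals[k] if reverse else totals[k]),
                                                labels[k]))
    else:
        raise UnknownAttribute(f"unknown sort key {by!r}")
    remap = {old: new for new, old in enumerate(order)}
    if which == "rows":
        cells = {(remap[r], c): v for (r, c), v in m.cells.items()}
        values = {(remap[r], c): v for (r, c), v in m.values.items()}
        row_labels = [labels[k] for k in order]
        col_labels = list(m.col_labels)
    else:
        cells = {(r, remap[c]): v for (r, c), v in m.cells.items()}
        values = {(r, remap[c]): v for (r, c), v in m.values.items()}
        row_labels = list(m.row_labels)
        col_labels = [labels[k] for k in order]
    return Matrix(
        row_axis=m.row_axis, col_axis=m.col_axis,
        row_labels=row_labels, col_labels=col_labels,
        cells=cells, statistic=m.statistic, values=values, dataset=m.dataset,
        n_unassigned=m.n_unassigned, n_dropped=m.n_dropped,
    )


CellRef = tuple[Union[int, str], Union[int, str]]


def _resolve_cell(m: Matrix, ref: CellRef) -> tuple[int, int]:
    r, c = ref
    if isinstance(r, str):
        if r not in m.row_labels:
            raise NoSuchCell(f"no row {r!r}")
        r = m.row_labels.index(r)
    if isinstance(c, str):
        if c not in m.col_labels:
            raise NoSuchCell(f"no column {c!r}")
        c = m.col_labels.index(c)
    if not (0 <= r < len(m.row_labels) and 0 <= c < len(m.col_labels)):
        raise NoSuchCell(f"cell ({ref[0]!r}, {ref[1]!r}) outside the matrix")
    return r, c


def grab_cells(
    m: Matrix,
    cells: Optional[Sequence[CellRef]] = None,
    predicate: Optional[Callable[[float], bool]] = None,
) -> Selection:
    """Union of the chosen cells' HSPs as a Selection ("grabbing").

    Cells are named by index or label pairs; alternatively ``predicate``
    selects every non-empty cell whose statistic satisfies a cut-off (e.g.
    ``lambda v: v < 1e-5`` on a mean-e-value matrix).
    """
    if (cells is None) == (predicate is None):
        raise ValueError("provide exactly one of cells= or predicate=")
    members: set[int] = set()
    if cells is not None:
        for ref in cells:
            rc = _resolve_cell(m, ref)
            members.update(m.cells.get(rc, ()))
    else:
        for rc, value in m.values.items():
            if predicate(value):
                members.update(m.cells[rc])
    return Selection(m.dataset, frozenset(members))


def grab_rows(m: Matrix, row_labels: Sequence[str]) -> Selection:
    """Grab every cell of the named rows."""
    refs = [(lab, c) for lab in row_labels for c in range(len(m.col_labels))]
    return grab_cells(m, cells=refs)


def grab_cols(m: Matrix, col_labels: Sequence[str]) -> Selection:
    """Grab every cell of the named columns."""
    refs = [(r, lab) for lab in col_labels for r in range(len(m.row_labels))]
    return grab_cells(m, cells=refs)


def matrix_to_tsv(m: Matrix) -> str:
    """TSV export: first row column labels, first column row labels, empty
    cells rendered as empty strings."""
    def fmt(v: float) -> str:
        if m.statistic[0] == "count":
            return str(int(v))
        return format(v, ".6g")

    lines = ["\t" + "\t".join(m.col_labels)]
    for r, row_label in enumerate(m.row_labels):
        row = [row_label]
        for c in range(len(m.col_labels)):
            v = m.values.get((r, c))
            row.append("" if v is None else fmt(v))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
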