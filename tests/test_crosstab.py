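"""Matrix viewer engine: binning, statistics, heat map, sort, grab."""

import math
import random

import pytest

from blasthits.crosstab import (build_category_axis, build_interval_axis,
                                build_taxonomy_axis, cross_tabulate, grab_cells,
                                grab_cols, heatmap_normalize, matrix_to_tsv,
                                sort_matrix)
from blasthits.errors import BadEdges, EmptyMatrix, NoSuchCell, UnknownAttribute
from blasthits.fixtures import SynthSpec, synth_dataset
from blasthits.taxonomy import ExpansionState, annotate_by_name
from conftest import make_dataset


def _dataset_with_evalues(evalues):
    return make_dataset(
        ["q1"], ["hit one"],
        [dict(evalue=e) for e in evalues],
    )


class TestIntervalAxis:
    def test_evalue_axis_bins(self):
        axis = build_interval_axis("evalue", [-10, -5])
        # dedicated 0 bin + underflow + one interval + overflow
        assert axis.labels == ["0", "(-inf,1e-10)", "[1e-10,1e-5)", "[1e-5,inf)"]

    def test_half_open_boundary(self):
        d = _dataset_with_evalues([1e-5, 1e-10, 0.0, 1e-12])
        axis = build_interval_axis("evalue", [-10, -5])
        labels = [axis.assign(d, i) for i in range(4)]
        assert labels == ["[1e-5,inf)", "[1e-10,1e-5)", "0", "(-inf,1e-10)"]

    def test_bad_edges_rejected(self):
        with pytest.raises(BadEdges):
            build_interval_axis("evalue", [])
        with pytest.raises(BadEdges):
            build_interval_axis("bit_score", [5, 5])
        with pytest.raises(UnknownAttribute):
            build_interval_axis("nope", [1, 2])

    @pytest.mark.parametrize("attribute", ["bit_score", "identity_pct", "align_len"])
    def test_random_values_match_brute_force(self, attribute, medium_dataset):
        d = medium_dataset
        rng = random.Random(1)
        edges = sorted(rng.sample(range(0, 1200), 4))
        axis = build_interval_axis(attribute, edges)
        for i, h in enumerate(d.hsps):
            v = getattr(h, attribute)
            if v < edges[0]:
                expected = axis.labels[0]
            elif v >= edges[-1]:
                expected = axis.labels[-1]
            else:
                k = next(j for j in range(len(edges) - 1)
                         if edges[j] <= v < edges[j + 1])
                expected = axis.labels[1 + k]
            assert axis.assign(d, i) == expected


class TestCrossTabulate:
    def test_conservation_over_axis_pairs(self, medium_dataset, toy_tree):
        d = medium_dataset
        annotate_by_name(d, toy_tree)
        axes = [
            build_interval_axis("evalue", [-20, -10, -5]),
            build_interval_axis("bit_score", [100, 500]),
            build_category_axis("query", d),
            build_category_axis("sequence", d),
            build_taxonomy_axis(toy_tree, ExpansionState()),
        ]
        for rows in axes:
            for cols in axes:
                m = cross_tabulate(d, rows, cols)
                assert m.total_count() == len(d.hsps)
                assert m.n_dropped == 0

    def test_collapse_all_single_root_row(self, toy_tree):
        d = synth_dataset(SynthSpec(n_queries=2, hits_per_query=3,
                                    taxid_pool={9606: 1.0}, seed=2))
        annotate_by_name(d, toy_tree)
        m = cross_tabulate(d, build_taxonomy_axis(toy_tree, ExpansionState()),
                           build_category_axis("query", d))
        populated_rows = {r for (r, _c) in m.cells}
        assert populated_rows == {m.row_labels.index("root")}
        for qid, qname in enumerate(d.queries):
            c = m.col_labels.index(qname)
            cell = m.values.get((m.row_labels.index("root"), c))
            assert cell == len(d.hsps_of_query(qid))

    def test_mean_evalue_per_taxon(self, toy_tree):
        d = synth_dataset(SynthSpec(n_queries=2, seed=3))
        annotate_by_name(d, toy_tree)
        m = cross_tabulate(d, build_taxonomy_axis(toy_tree, ExpansionState()),
                           build_category_axis("query", d),
                           statistic=("mean", "evalue"))
        for (r, c), members in m.cells.items():
            expected = sum(d.hsps[i].evalue for i in members) / len(members)
            assert m.values[(r, c)] == pytest.approx(expected)

    def test_cells_match_brute_force(self, medium_dataset):
        d = medium_dataset
        rows = build_interval_axis("evalue", [-40, -20, -5])
        cols = build_category_axis("query", d)
        m = cross_tabulate(d, rows, cols)
        for (r, c), members in m.cells.items():
            oracle = [i for i in range(len(d.hsps))
                      if rows.assign(d, i) == m.row_labels[r]
                      and cols.assign(d, i) == m.col_labels[c]]
            assert sorted(members) == oracle

    def test_count_units(self, small_dataset):
        d = small_dataset
        rows = build_interval_axis("evalue", [-40])
        cols = build_category_axis("query", d)
        hsp_total = cross_tabulate(d, rows, cols).total_count()
        pair_m = cross_tabulate(d, rows, cols, statistic=("count", "pair"))
        assert hsp_total == len(d.hsps)
        assert sum(pair_m.values.values()) <= hsp_total

    def test_bin_refinement_preserves_counts(self, medium_dataset):
        d = medium_dataset
        cols = build_category_axis("query", d)
        coarse = cross_tabulate(d, build_interval_axis("evalue", [-20, -5]), cols)
        fine = cross_tabulate(d, build_interval_axis("evalue", [-20, -12, -5]), cols)
        ci = coarse.row_labels.index("[1e-20,1e-5)")
        f1 = fine.row_labels.index("[1e-20,1e-12)")
        f2 = fine.row_labels.index("[1e-12,1e-5)")
        assert coarse.row_total(ci) == fine.row_total(f1) + fine.row_total(f2)

    def test_expansion_moves_counts_to_children(self, toy_tree, medium_dataset):
        d = medium_dataset
        annotate_by_name(d, toy_tree)
        cols = build_category_axis("query", d)
        collapsed = cross_tabulate(d, build_taxonomy_axis(toy_tree, ExpansionState()),
                                   cols)
        state = ExpansionState({1})
        expanded = cross_tabulate(d, build_taxonomy_axis(toy_tree, state), cols)
        root_total = collapsed.row_total(collapsed.row_labels.index("root"))
        child_rows = [expanded.row_labels.index(toy_tree.name(c))
                      for c in toy_tree.children(1)]
        assert root_total == sum(expanded.row_total(r) for r in child_rows)
        assert expanded.total_count() == collapsed.total_count() == len(d.hsps)


class TestHeatmap:
    def test_linear_map(self):
        d = _dataset_with_evalues([1e-3] * 2 + [1e-8] * 4 + [1e-15] * 6)
        m = cross_tabulate(d, build_interval_axis("evalue", [-12, -5]),
                           build_category_axis("query", d))
        norm = heatmap_normalize(m)
        assert sorted(norm.values.values()) == [0.0, 0.5, 1.0]

    def test_degenerate_all_equal(self):
        d = _dataset_with_evalues([1e-3, 1e-8, 1e-15])
        m = cross_tabulate(d, build_interval_axis("evalue", [-12, -5]),
                           build_category_axis("query", d))
        norm = heatmap_normalize(m)
        assert set(norm.values.values()) == {0.5}

    def test_evalue_statistic_normalised_on_log_scale(self):
        d = _dataset_with_evalues([1e-10, 1e-5, 1.0])
        m = cross_tabulate(d, build_interval_axis("evalue", [-8, -2]),
                           build_category_axis("query", d),
                           statistic=("mean", "evalue"))
        norm = heatmap_normalize(m)
        assert sorted(norm.values.values()) == pytest.approx([0.0, 0.5, 1.0])

    def test_empty_matrix_raises(self):
        d = make_dataset(["q1"], ["hit one"], [])
        m = cross_tabulate(d, build_interval_axis("evalue", [-5]),
                           build_category_axis("query", d))
        with pytest.raises(EmptyMatrix):
            heatmap_normalize(m)


class TestSort:
    def test_desc_then_asc_reverses(self, medium_dataset):
        d = medium_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-40, -20, -5]))
        desc = sort_matrix(m, by="row_total", direction="desc")
        asc = sort_matrix(m, by="row_total", direction="asc")
        totals = [desc.row_total(r) for r in range(len(desc.row_labels))]
        if len(set(totals)) == len(totals):  # exact reversal when distinct
            assert desc.row_labels == asc.row_labels[::-1]
        assert totals == sorted(totals, reverse=True)

    def test_ties_break_by_label(self):
        d = make_dataset(["b query", "a query"], ["hit one"],
                         [dict(qid=0), dict(qid=1)])
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-5]))
        out = sort_matrix(m, by="row_total", direction="desc")
        assert out.row_labels == ["a query", "b query"]

    def test_sort_preserves_cell_contents(self, medium_dataset):
        d = medium_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-40, -5]))
        out = sort_matrix(m, by="label", direction="asc")
        assert out.total_count() == m.total_count()
        for r, lab in enumerate(out.row_labels):
            old_r = m.row_labels.index(lab)
            assert out.row_total(r) == m.row_total(old_r)


class TestGrab:
    def test_grab_most_significant_column(self, medium_dataset):
        d = medium_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-100, -50, -20, -10, -4]))
        sel = grab_cols(m, ["0", "(-inf,1e-100)"])
        for i in sel.members:
            assert d.hsps[i].evalue < 1e-100
        oracle = {i for i, h in enumerate(d.hsps) if h.evalue < 1e-100}
        assert sel.members == oracle

    def test_grab_all_cells(self, medium_dataset):
        d = medium_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-20]))
        refs = [(r, c) for r in range(len(m.row_labels))
                for c in range(len(m.col_labels))]
        assert len(grab_cells(m, cells=refs)) == len(d.hsps)

    def test_predicate_cutoff_matches_oracle(self, medium_dataset):
        d = medium_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-40, -20, -5]))
        k = 3
        sel = grab_cells(m, predicate=lambda v: v >= k)
        oracle = {i for members in m.cells.values() if len(members) >= k
                  for i in members}
        assert sel.members == oracle

    def test_missing_cell_raises(self, small_dataset):
        d = small_dataset
        m = cross_tabulate(d, build_category_axis("query", d),
                           build_interval_axis("evalue", [-5]))
        with pytest.raises(NoSuchCell):
            grab_cells(m, cells=[("no such row", 0)])


class TestTsvExport:
    def test_layout_and_empty_cells(self):
        d = _dataset_with_evalues([1e-8, 1e-8, 1e-2])
        m = cross_tabulate(d, build_interval_axis("evalue", [-5]),
                           build_category_axis("query", d))
        tsv = matrix_to_tsv(m)
        lines = tsv.splitlines()
        assert lines[0] == "\tq1"
        table = {row.split("\t")[0]: row.split("\t")[1] for row in lines[1:]}
        assert table["(-inf,1e-5)"] == "2"
        assert table["[1e-5,inf)"] == "1"
        assert table["0"] == ""  # empty cell renders as empty string
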