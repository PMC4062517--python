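"""Taxonomy loading, annotation and frontier resolution."""

import random

import pytest

from blasthits.errors import FormatError, UnknownTaxid
from blasthits.fixtures import SynthSpec, planted_taxid, synth_dataset, write_gi_mapping
from blasthits.model import Dataset, SeqEntry
from blasthits.taxonomy import (TOY_TAXA, ExpansionState, annotate_by_gi,
                                annotate_by_name, frontier, load_taxdump,
                                resolve_defline_taxid, visible_ancestor,
                                write_toy_taxdump)


class TestLoadTaxdump:
    def test_toy_taxdump_loads_all_nodes(self, taxdump_dir):
        tree = load_taxdump(taxdump_dir / "nodes.dmp", taxdump_dir / "names.dmp")
        assert len(tree) == len(TOY_TAXA)
        assert tree.name(9606) == "Homo sapiens"
        assert tree.name(33511) == "Deuterostomia"

    def test_only_scientific_names_loaded(self, taxdump_dir):
        tree = load_taxdump(taxdump_dir / "nodes.dmp", taxdump_dir / "names.dmp")
        # names.dmp carries synonym/common-name rows that must be ignored
        assert "man" not in tree.name_index
        assert "bacillus coli" not in tree.name_index
        assert tree.name(562) == "Escherichia coli"

    def test_missing_name_falls_back(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text("1\t|\t1\t|\tno rank\t|\n7\t|\t1\t|\tspecies\t|\n")
        names.write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        tree = load_taxdump(nodes, names)
        assert tree.name(7) == "taxid:7"

    def test_self_parent_cycle_rejected(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text("1\t|\t1\t|\tno rank\t|\n5\t|\t5\t|\tgenus\t|\n")
        names.write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(FormatError):
            load_taxdump(nodes, names)

    def test_two_node_cycle_rejected(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text("1\t|\t1\t|\tno rank\t|\n"
                         "5\t|\t6\t|\tgenus\t|\n5\t|\t6\t|\tgenus\t|\n"
                         "6\t|\t5\t|\tgenus\t|\n")
        names.write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(FormatError):
            load_taxdump(nodes, names)


class TestAnnotateByGi:
    def test_direct_lookup(self, tmp_path, toy_tree):
        d = Dataset(sequences=[SeqEntry("gi|12345|ref|X| something")])
        mapping = tmp_path / "gi.map"
        mapping.write_text("12345\t9606\n")
        report = annotate_by_gi(d, mapping, tree=toy_tree)
        assert d.sequences[0].taxid == 9606
        assert (report.assigned, report.unassigned) == (1, 0)

    def test_defline_without_gi_counts_unassigned(self, tmp_path, toy_tree):
        d = Dataset(sequences=[SeqEntry("no identifier here")])
        mapping = tmp_path / "gi.map"
        mapping.write_text("12345\t9606\n")
        report = annotate_by_gi(d, mapping, tree=toy_tree)
        assert d.sequences[0].taxid is None
        assert report.unassigned == 1

    def test_unknown_taxid_counts_unassigned(self, tmp_path, toy_tree):
        d = Dataset(sequences=[SeqEntry("gi|1|x y")])
        mapping = tmp_path / "gi.map"
        mapping.write_text("1\t999999999\n")
        report = annotate_by_gi(d, mapping, tree=toy_tree)
        assert report.unassigned == 1

    def test_existing_taxid_not_overwritten(self, tmp_path, toy_tree):
        d = Dataset(sequences=[SeqEntry("gi|1|x y", taxid=10090)])
        mapping = tmp_path / "gi.map"
        mapping.write_text("1\t9606\n")
        report = annotate_by_gi(d, mapping, tree=toy_tree)
        assert d.sequences[0].taxid == 10090
        assert report.skipped_existing == 1
        annotate_by_gi(d, mapping, tree=toy_tree, overwrite=True)
        assert d.sequences[0].taxid == 9606

    def test_synthetic_recovery_matches_oracle(self, tmp_path, toy_tree):
        d = synth_dataset(SynthSpec(n_queries=15, seed=8))
        mapping = write_gi_mapping(d, tmp_path / "gi.map")
        report = annotate_by_gi(d, mapping, tree=toy_tree)
        plantable = sum(1 for s in d.sequences
                        if planted_taxid(s.defline) is not None)
        assert report.assigned == plantable
        assert report.unassigned == len(d.sequences) - plantable
        for s in d.sequences:
            assert s.taxid == planted_taxid(s.defline)


class TestAnnotateByName:
    def test_bracketed_organism_field(self, toy_tree):
        d = Dataset(sequences=[SeqEntry("gi|1|x kinase [Homo sapiens]")])
        annotate_by_name(d, toy_tree)
        assert d.sequences[0].taxid == 9606

    def test_longest_match_wins(self, toy_tree):
        taxid, ambiguous = resolve_defline_taxid(
            "protein from Drosophila melanogaster strain, Drosophila genus",
            toy_tree)
        assert not ambiguous
        assert taxid == 7227  # species outranks the bare genus match

    def test_genus_only_match(self, toy_tree):
        taxid, ambiguous = resolve_defline_taxid("some Caenorhabditis protein",
                                                 toy_tree)
        assert taxid == 6237 and not ambiguous

    def test_equal_length_tie_is_ambiguous(self, toy_tree):
        # two species names of equal character length, no brackets
        taxid, ambiguous = resolve_defline_taxid(
            "chimeric Danio rerio Homo sapiens construct"[9:], toy_tree)
        # 'Danio rerio' (11) vs 'Homo sapiens' (12): longest wins, no tie
        assert taxid == 9606 and not ambiguous
        d = Dataset(sequences=[SeqEntry("between Homo sapiens and Mus musculus")])
        report = annotate_by_name(d, toy_tree)
        assert d.sequences[0].taxid is None
        assert report.ambiguous == 1

    def test_synthetic_full_recovery(self, toy_tree):
        d = synth_dataset(SynthSpec(n_queries=15, seed=8))
        report = annotate_by_name(d, toy_tree)
        plantable = sum(1 for s in d.sequences
                        if planted_taxid(s.defline) is not None)
        assert report.assigned == plantable
        assert report.unassigned == len(d.sequences) - plantable
        for s in d.sequences:
            assert s.taxid == planted_taxid(s.defline)


def _oracle_visible_ancestor(taxid, tree, state):
    """Independent route: deepest visible node on the root path, where the
    visible set is enumerated from scratch over all nodes."""
    visible = {
        t for t in tree.nodes
        if all(a in state.expanded for a in tree.path_from_root(t)[:-1])
    }
    on_path = [t for t in tree.path_from_root(taxid) if t in visible]
    return on_path[-1]


class TestVisibleAncestor:
    def test_collapse_all_maps_to_root(self, toy_tree):
        state = ExpansionState()
        assert visible_ancestor(9606, toy_tree, state) == 1
        assert visible_ancestor(1, toy_tree, state) == 1

    def test_expand_all_maps_to_self(self, toy_tree):
        state = ExpansionState(set(toy_tree.nodes))
        for taxid in (9606, 6239, 1, 33208):
            assert visible_ancestor(taxid, toy_tree, state) == taxid

    def test_unknown_taxid_raises(self, toy_tree):
        with pytest.raises(UnknownTaxid):
            visible_ancestor(424242, toy_tree, ExpansionState())

    def test_partial_expansion(self, toy_tree):
        # expand the path down to Deuterostomia but keep it collapsed
        state = ExpansionState({1, 131567, 2759, 33154, 33208, 6072, 33213})
        assert visible_ancestor(9606, toy_tree, state) == 33511  # Deuterostomia
        assert visible_ancestor(6239, toy_tree, state) == 33317  # Protostomia

    @pytest.mark.parametrize("seed", range(10))
    def test_random_states_match_oracle(self, toy_tree, seed):
        rng = random.Random(seed)
        nodes = list(toy_tree.nodes)
        state = ExpansionState({t for t in nodes if rng.random() < 0.4})
        for taxid in rng.sample(nodes, 12):
            assert visible_ancestor(taxid, toy_tree, state) == \
                _oracle_visible_ancestor(taxid, toy_tree, state)

    @pytest.mark.parametrize("seed", range(5))
    def test_frontier_covers_every_node_once(self, toy_tree, seed):
        rng = random.Random(seed)
        state = ExpansionState({t for t in toy_tree.nodes if rng.random() < 0.5})
        front = frontier(toy_tree, state)
        assert len(front) == len(set(front))
        for taxid in toy_tree.nodes:
            anc = visible_ancestor(taxid, toy_tree, state)
            assert anc in front
            # idempotence under the same state
            assert visible_ancestor(anc, toy_tree, state) == anc
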