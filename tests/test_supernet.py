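import networkx as nx
import pytest

from emmernet.io import TaxonSet, read_trees
from emmernet.splits import Split, SplitSystem, restrict_split, splits_from_tree
from emmernet.supernet import (FilterParams, SupernetError, boxes_involving,
                               build_splits_graph, filter_splits,
                               split_sides_from_graph, support_count, zclosure)
from emmernet.synthdata import gen_discordant_trees
from emmernet.trees import PhyloTree, random_binary_tree


def system(taxa: str, *pairs) -> SplitSystem:
    return SplitSystem(TaxonSet(list(taxa)),
                       [Split(frozenset(a), frozenset(b)) for a, b in pairs])


class TestZClosure:
    def test_full_inputs_identity(self):
        sys = system("abcd", ("ab", "cd"), ("a", "bcd"))
        out = zclosure([sys], runs=3, seed=0)
        assert set(out.splits) == set(sys.splits)

    def test_hand_applied_rule(self):
        s1 = system("abc", ("ab", "c"))
        s2 = system("bcd", ("b", "cd"))
        out = zclosure([s1, s2], runs=3, seed=0)
        assert Split(frozenset("ab"), frozenset("cd")) in out.splits

    def test_disjoint_inputs_completed_without_interaction(self):
        s1 = system("ab", ("a", "b"))
        s2 = system("cd", ("c", "d"))
        out = zclosure([s1, s2], runs=2, seed=1)
        domains = {s.support_domain for s in out.splits}
        assert domains == {frozenset("abcd")}
        assert Split(frozenset("a"), frozenset("bcd")) in out.splits

    def test_empty_input(self):
        out = zclosure([], runs=1, seed=0)
        assert len(out) == 0

    def test_no_signal_loss_on_clean_partial_trees(self, rng):
        """Restricted to any input tree's taxa, the closure contains all of
        that tree's nontrivial splits when the inputs agree (no conflict)."""
        labs = [f"t{i}" for i in range(7)]
        sp = random_binary_tree(labs, rng)
        trees, _ = gen_discordant_trees(sp, 4, hybrid_edges=0,
                                        taxon_dropout=0.25, seed=11)
        utrees = [PhyloTree(t.root.copy(), rooted=False) for t in trees]
        full = zclosure(utrees, runs=5, seed=2)
        for t in utrees:
            for s in splits_from_tree(t).nontrivial():
                restrictions = [restrict_split(f, t.taxa) for f in full.splits]
                assert any(r == s for r in restrictions if r is not None)


class TestSupportCount:
    def test_split_in_every_tree(self):
        trees = read_trees("((a,b),(c,d));\n((a,b),(c,d));")
        s = Split(frozenset("ab"), frozenset("cd"))
        assert support_count(s, trees) == 2

    def test_vacuous_support_when_invisible(self):
        trees = read_trees("((a,b),(c,d));")
        s = Split(frozenset("ef"), frozenset("gh"))
        assert support_count(s, trees) == 1

    def test_conflicting_tree_contributes_zero(self):
        trees = read_trees("((a,c),(b,d));")
        s = Split(frozenset("ab"), frozenset("cd"))
        assert support_count(s, trees) == 0

    def test_trivial_restriction_supports(self):
        trees = read_trees("((a,b),(c,d));")
        s = Split(frozenset("a"), frozenset("efg"))
        assert support_count(s, trees) == 1


class TestFilterSplits:
    def make_inputs(self):
        return read_trees("((a,b),(c,d));\n((a,b),(c,d));\n((a,c),(b,d));")

    def test_zero_threshold_identity(self):
        inputs = self.make_inputs()
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"))
        out = filter_splits(sys, inputs, FilterParams(0, strict_greater=False))
        assert set(out.splits) == set(sys.splits)

    def test_full_threshold_keeps_unanimous_only(self):
        inputs = self.make_inputs()
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"))
        out = filter_splits(sys, inputs, FilterParams(3, strict_greater=False))
        assert out.nontrivial() == []
        out2 = filter_splits(sys, inputs, FilterParams(2, strict_greater=False))
        assert [s.key() for s in out2.nontrivial()] == \
            [Split(frozenset("ab"), frozenset("cd")).key()]

    def test_antitone_in_threshold(self):
        inputs = self.make_inputs()
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"), ("a", "bcd"))
        kept = [set(filter_splits(sys, inputs,
                                  FilterParams(m, strict_greater=False)).splits)
                for m in range(4)]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_trivial_always_retained(self):
        inputs = self.make_inputs()
        sys = system("abcd", ("a", "bcd"))
        out = filter_splits(sys, inputs, FilterParams(99, strict_greater=True))
        assert len(out) == 1

    def test_support_counts_annotated(self):
        inputs = self.make_inputs()
        sys = system("abcd", ("ab", "cd"))
        (s,) = filter_splits(sys, inputs, FilterParams(0)).splits
        assert s.support_count == 2

    def test_planted_noise_filtered_out(self):
        """Splits supported by fewer inputs than the threshold vanish;
        the consensus backbone survives."""
        backbone = read_trees("((a,b),(c,d),e);" * 5)
        noise_tree = read_trees("((a,c),(b,d),e);")
        inputs = backbone + noise_tree
        sys = system("abcde", ("ab", "cde"), ("cd", "abe"), ("ac", "bde"))
        out = filter_splits(sys, inputs, FilterParams(4, strict_greater=True))
        kept = {s.key() for s in out.nontrivial()}
        assert kept == {Split(frozenset("ab"), frozenset("cde")).key(),
                        Split(frozenset("cd"), frozenset("abe")).key()}


class TestSplitsGraph:
    def test_compatible_system_gives_tree(self):
        (t,) = read_trees("((a,b),(c,d),e);")
        sys = splits_from_tree(t)
        sg = build_splits_graph(sys)
        assert sg.graph.number_of_edges() == len(sys)
        assert nx.is_tree(nx.Graph(sg.graph))

    def test_two_incompatible_splits_box(self):
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"))
        sg = build_splits_graph(sys)
        assert sg.graph.number_of_nodes() == 4
        assert sg.graph.number_of_edges() == 4

    def test_three_incompatible_splits_cube(self):
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"), ("ad", "bc"))
        sg = build_splits_graph(sys)
        assert sg.graph.number_of_nodes() == 8
        assert sg.graph.number_of_edges() == 12

    def test_deleting_edge_class_recovers_split(self):
        sys = system("abcde", ("ab", "cde"), ("abc", "de"))
        sg = build_splits_graph(sys)
        for i, s in enumerate(sg.splits):
            sides = split_sides_from_graph(sg, i)
            assert set(sides) == {s.side_a, s.side_b}

    def test_node_cap_enforced(self):
        sys = system("abcd", ("ab", "cd"), ("ac", "bd"), ("ad", "bc"))
        with pytest.raises(SupernetError):
            build_splits_graph(sys, node_cap=4)


class TestBoxes:
    def test_reticulate_taxon_participates_in_box(self):
        sys = system("abcdh", ("ah", "bcd"), ("bh", "acd"))
        assert boxes_involving(sys, "h")

    def test_compatible_system_has_no_boxes(self):
        sys = system("abcd", ("ab", "cd"), ("a", "bcd"))
        assert boxes_involving(sys, "a") == []
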