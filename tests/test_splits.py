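import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import four_gametes_present
from conftest import make_alignment
from emmernet.io import SeqAlignment, TaxonSet
from emmernet.splits import (Split, SplitError, all_pairwise_compatible,
                             are_compatible, restrict_split,
                             split_from_column, split_from_marker,
                             splits_from_tree)
from emmernet.synthdata import gen_hybrid_markers
from emmernet.trees import random_binary_tree
from emmernet.io import read_trees


def aln(cols: list[str], labels=None) -> SeqAlignment:
    n = len(cols[0])
    labels = labels or list("wxyz"[:n]) if n <= 4 else [f"t{i}" for i in range(n)]
    rows = ["".join(c[i] for c in cols) for i in range(n)]
    return SeqAlignment(TaxonSet(labels), rows)


class TestSplitType:
    def test_canonical_side_order(self):
        s = Split(frozenset("cd"), frozenset("ab"))
        assert s.side_a == frozenset("ab")

    def test_unordered_equality(self):
        assert Split(frozenset("ab"), frozenset("cd")) == \
            Split(frozenset("cd"), frozenset("ab"))

    def test_overlapping_sides_rejected(self):
        with pytest.raises(SplitError):
            Split(frozenset("ab"), frozenset("bc"))

    def test_trivial_flagging(self):
        assert Split(frozenset("a"), frozenset("bc")).is_trivial
        assert not Split(frozenset("ab"), frozenset("cd")).is_trivial


class TestSplitFromColumn:
    def test_binary_column(self):
        (s,) = split_from_column(aln(["AACC"]), 0)
        assert s == Split(frozenset("wx"), frozenset("yz"))

    def test_missing_taxon_excluded(self):
        (s,) = split_from_column(aln(["ANCC"]), 0)
        assert s == Split(frozenset("w"), frozenset("yz"))
        assert s.support_domain == frozenset("wyz")

    def test_multistate_one_split_per_state(self):
        out = split_from_column(aln(["ACGG"]), 0)
        assert len(out) == 3
        assert Split(frozenset("w"), frozenset("xyz")) in out
        assert Split(frozenset("x"), frozenset("wyz")) in out
        assert Split(frozenset("yz"), frozenset("wx")) in out

    def test_monomorphic_rejected(self):
        with pytest.raises(SplitError):
            split_from_column(aln(["AAAA"]), 0)


class TestSplitFromMarker:
    def test_present_absent(self):
        mm, _ = gen_hybrid_markers([2, 2], 2, seed=0)
        s = split_from_marker(mm, "M01")
        assert s == Split(frozenset({"p1_01", "p1_02"}),
                          frozenset({"p2_01", "p2_02"}))

    def test_singleton_marker_flagged_uninformative(self):
        from emmernet.io import read_marker_matrix
        mm = read_marker_matrix("taxon\tM1\na\t1\nb\t0\nc\t0\nd\t0\n")
        s = split_from_marker(mm, "M1")
        assert s.is_trivial and not s.informative

    def test_missing_call_excluded(self):
        from emmernet.io import read_marker_matrix
        mm = read_marker_matrix("taxon\tM1\na\t1\nb\tNA\nc\t0\nd\t1\n")
        s = split_from_marker(mm, "M1")
        assert s.support_domain == frozenset("acd")

    def test_constant_marker_rejected(self):
        from emmernet.io import read_marker_matrix
        mm = read_marker_matrix("taxon\tM1\na\t1\nb\t1\n")
        with pytest.raises(SplitError):
            split_from_marker(mm, "M1")


class TestSplitsFromTree:
    def test_quartet(self):
        (t,) = read_trees("((a,b),(c,d));")
        sys = splits_from_tree(t)
        assert Split(frozenset("ab"), frozenset("cd")) in sys.nontrivial()
        assert len(sys.nontrivial()) == 1

    def test_star_only_trivial(self):
        (t,) = read_trees("(a,b,c,d);")
        assert splits_from_tree(t).nontrivial() == []

    def test_caterpillar_five_leaves(self):
        (t,) = read_trees("(a,(b,(c,(d,e))));")
        assert len(splits_from_tree(t).nontrivial()) == 2

    def test_tree_splits_pairwise_compatible(self, rng):
        for _ in range(5):
            t = random_binary_tree([f"t{i}" for i in range(7)], rng)
            sys = splits_from_tree(t)
            assert all_pairwise_compatible(sys.splits)
            # full binary system has at most 2n-3 splits
            assert len(sys.splits) <= 2 * 7 - 3


class TestCompatibility:
    def test_classic_incompatible_pair(self):
        assert not are_compatible(Split(frozenset("ab"), frozenset("cd")),
                                  Split(frozenset("ac"), frozenset("bd")))

    def test_nested_compatible(self):
        assert are_compatible(Split(frozenset("ab"), frozenset("cd")),
                              Split(frozenset("a"), frozenset("bcd")))

    def test_partial_overlap_compatible_on_common_domain(self):
        s = Split(frozenset("ab"), frozenset("cd"))
        t = Split(frozenset("ae"), frozenset("df"))
        assert are_compatible(s, t)  # common domain {a,d} < 4 taxa

    def test_symmetric_and_reflexive(self, rng):
        taxa = list("abcdef")
        for _ in range(20):
            k1, k2 = rng.randint(1, 5), rng.randint(1, 5)
            a = frozenset(rng.sample(taxa, k1))
            s = Split(a, frozenset(taxa) - a)
            b = frozenset(rng.sample(taxa, k2))
            t = Split(b, frozenset(taxa) - b)
            assert are_compatible(s, t) == are_compatible(t, s)
            assert are_compatible(s, s)

    def test_four_gamete_equivalence(self, rng):
        """Binary-column split incompatibility == the four-gamete test."""
        checked = 0
        for seed in range(30):
            r = random.Random(seed)
            a = make_alignment(r, 6, 8, alphabet="AC")
            for i, j in itertools.combinations(range(8), 2):
                try:
                    (si,) = split_from_column(a, i)
                    (sj,) = split_from_column(a, j)
                except Exception:
                    continue
                assert are_compatible(si, sj) == (not four_gametes_present(a, i, j))
                checked += 1
        assert checked > 100


class TestRestrict:
    def test_basic(self):
        s = Split(frozenset("ab"), frozenset("cd"))
        assert restrict_split(s, {"a", "c"}) == Split(frozenset("a"), frozenset("c"))

    def test_side_emptied_returns_none(self):
        s = Split(frozenset("ab"), frozenset("cd"))
        assert restrict_split(s, {"a", "b"}) is None

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.sampled_from("abcdef"), min_size=0, max_size=6),
           st.sets(st.sampled_from("abcdef"), min_size=0, max_size=6))
    def test_composition(self, keep1, keep2):
        s = Split(frozenset("abc"), frozenset("def"))
        step = restrict_split(s, keep1)
        two = restrict_split(step, keep2) if step else None
        direct = restrict_split(s, keep1 & keep2)
        assert two == direct
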