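import random

import pytest

from _oracles import brute_force_fitch
from conftest import make_alignment
from emmernet.io import SeqAlignment, TaxonSet, read_alignment, read_trees
from emmernet.parsimony import (ParsimonyError, bootstrap_support,
                                fitch_score, incongruence_ratio,
                                majority_consensus, mp_search,
                                strict_consensus)
from emmernet.trees import PhyloTree, random_binary_tree


def quartet_alignment(cols: list[str]) -> SeqAlignment:
    rows = ["".join(c[i] for c in cols) for i in range(4)]
    return SeqAlignment(TaxonSet(list("abcd")), rows)


class TestFitch:
    def test_matching_topology_one_change(self):
        (t,) = read_trees("((a,b),(c,d));")
        assert fitch_score(t, quartet_alignment(["AACC"])) == 1

    def test_conflicting_topology_two_changes(self):
        (t,) = read_trees("((a,c),(b,d));")
        assert fitch_score(t, quartet_alignment(["AACC"])) == 2

    def test_missing_is_wildcard(self):
        (t,) = read_trees("((a,b),(c,d));")
        assert fitch_score(t, quartet_alignment(["AAC?"])) == 1
        assert fitch_score(t, quartet_alignment(["AA-C"])) == 1

    def test_gap_as_fifth_state_mode(self):
        (t,) = read_trees("((a,b),(c,d));")
        aln = quartet_alignment(["AA--"])
        assert fitch_score(t, aln) == 0
        assert fitch_score(t, aln, gap_as_state=True) == 1

    def test_leaf_without_sequence_rejected(self):
        (t,) = read_trees("((a,b),(c,e));")
        with pytest.raises(ParsimonyError):
            fitch_score(t, quartet_alignment(["AACC"]))

    def test_matches_bruteforce_enumeration(self):
        for seed in range(8):
            r = random.Random(seed)
            tree = random_binary_tree([f"t{i}" for i in range(6)], r)
            aln = make_alignment(r, 6, 10, alphabet="ACGTN-")
            assert fitch_score(tree, aln) == brute_force_fitch(tree, aln)

    def test_invariant_under_rerooting(self, rng):
        aln = make_alignment(rng, 6, 12)
        (t1,) = read_trees("((t0,t1),(t2,(t3,(t4,t5))));")
        (t2,) = read_trees("(((t0,t1),t2),((t4,t5),t3));")
        # same unrooted topology, different rootings
        assert t1.same_topology(t2)
        assert fitch_score(t1, aln) == fitch_score(t2, aln)

    def test_multifurcation_scored_as_given(self):
        (star,) = read_trees("(a,b,c,d);")
        (res,) = read_trees("((a,b),(c,d));")
        assert fitch_score(star, quartet_alignment(["ACGT"])) == 3
        # the unresolved star cannot group the two state pairs
        assert fitch_score(star, quartet_alignment(["AACC"])) == 2
        assert fitch_score(res, quartet_alignment(["AACC"])) == 1


class TestMPSearch:
    def test_quartet_exact(self):
        aln = quartet_alignment(["AACC", "AACC", "GGTT"])
        found = mp_search(aln)
        assert len(found) == 1
        assert frozenset("ab") in found[0].tree.clusters() or \
            frozenset("cd") in found[0].tree.clusters()
        assert found[0].score == 3

    def test_duplicate_columns_double_score(self, rng):
        aln = make_alignment(rng, 5, 8)
        doubled = aln.select_columns(list(range(8)) * 2)
        s1 = mp_search(aln)
        s2 = mp_search(doubled)
        assert s2[0].score == 2 * s1[0].score
        assert {t.tree.topology_key() for t in s1} == \
            {t.tree.topology_key() for t in s2}

    def test_heuristic_matches_exhaustive_mostly(self):
        """10-jumble NNI search finds the exact optimum on nearly all
        small random alignments."""
        hits = 0
        trials = 25
        for seed in range(trials):
            r = random.Random(seed)
            aln = make_alignment(r, 7, 10)
            exact = mp_search(aln, exhaustive_limit=9)[0].score
            heur = mp_search(aln, n_jumbles=10, seed=seed,
                             exhaustive_limit=4)[0].score
            assert heur >= exact
            hits += heur == exact
        assert hits >= 0.95 * trials

    def test_too_few_taxa_rejected(self):
        aln = SeqAlignment(TaxonSet(["a", "b"]), ["A", "C"])
        with pytest.raises(ParsimonyError):
            mp_search(aln)


class TestConsensus:
    def test_strict_identical_trees(self):
        trees = read_trees("((a,b),(c,d),e);\n((a,b),(c,d),e);")
        cons = strict_consensus(trees)
        assert cons.same_topology(trees[0])

    def test_strict_conflict_collapses_to_star(self):
        trees = read_trees("((a,b),c,d);\n((a,c),b,d);")
        cons = strict_consensus(trees)
        assert cons.clusters() == set()

    def test_strict_consensus_splits_subset_of_inputs(self, rng):
        labs = [f"t{i}" for i in range(6)]
        trees = [PhyloTree(random_binary_tree(labs, rng).root, rooted=False)
                 for _ in range(3)]
        from emmernet.splits import splits_from_tree
        cons_splits = set(splits_from_tree(strict_consensus(trees)).nontrivial())
        for t in trees:
            assert cons_splits <= set(splits_from_tree(t).nontrivial())

    def test_majority_all_identical(self):
        trees = read_trees("((a,b),(c,d),e);" * 3)
        cons = majority_consensus(trees)
        assert set(cons.supports.values()) == {100.0}

    def test_majority_two_of_three(self):
        trees = read_trees("((a,b),c,d,e);\n((a,b),c,d,e);\n((a,c),b,d,e);")
        cons = majority_consensus(trees)
        assert cons.supports[frozenset("cde")] == pytest.approx(66.7, abs=0.1)
        assert frozenset("bde") not in cons.supports

    def test_differing_leaf_sets_rejected(self):
        trees = read_trees("((a,b),c,d);\n((a,b),c,e);")
        with pytest.raises(Exception):
            strict_consensus(trees)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        aln = quartet_alignment(["AACC", "AACC", "AGCT", "AACC"])
        c1 = bootstrap_support(aln, replicates=30, seed=5)
        c2 = bootstrap_support(aln, replicates=30, seed=5)
        assert c1.supports == c2.supports

    def test_overwhelming_signal_near_certainty(self):
        aln = quartet_alignment(["AACC"] * 10)
        cons = bootstrap_support(aln, replicates=100, seed=1)
        (support,) = cons.supports.values()
        assert support > 95

    def test_balanced_conflict_near_half(self):
        # two equally frequent, perfectly conflicting patterns
        aln = quartet_alignment(["AACC"] * 6 + ["ACAC"] * 6)
        cons = bootstrap_support(aln, replicates=200, seed=2)
        for support in cons.supports.values():
            assert 35 < support < 65


class TestIncongruence:
    def test_published_style_ratio(self):
        assert incongruence_ratio(652, [377]) == pytest.approx(1.73, abs=0.005)

    def test_self_ratio_is_one(self):
        assert incongruence_ratio(42, [42]) == 1.0

    def test_zero_sum_rejected(self):
        with pytest.raises(ParsimonyError):
            incongruence_ratio(5, [0, 0])

    def test_conflicting_loci_exceed_one(self):
        # two binary characters supporting opposite quartets
        l1 = quartet_alignment(["AACC"] * 2)
        l2 = quartet_alignment(["ACAC"] * 2)
        concat = quartet_alignment(["AACC"] * 2 + ["ACAC"] * 2)
        s1 = mp_search(l1)[0].score
        s2 = mp_search(l2)[0].score
        sc = mp_search(concat)[0].score
        assert s1 == 2 and s2 == 2 and sc == 6
        assert incongruence_ratio(sc, [s1, s2]) == pytest.approx(1.5)

    def test_superadditivity_on_synthetic_data(self):
        """Concatenated MP score >= sum of per-locus scores, always."""
        for seed in range(6):
            r = random.Random(seed)
            labs = [f"t{i}" for i in range(6)]
            loci = [make_alignment(r, 6, 8, labels=labs) for _ in range(3)]
            concat_rows = ["".join(a.row(l) for a in loci) for l in labs]
            concat = SeqAlignment(TaxonSet(labs), concat_rows)
            sc = mp_search(concat, exhaustive_limit=7)[0].score
            parts = sum(mp_search(a, exhaustive_limit=7)[0].score for a in loci)
            assert sc >= parts
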