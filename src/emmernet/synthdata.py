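"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, each returning its data plus a :class:`PlantedTruth`
recording what was planted so recovery can be scored without re-inspecting
generator internals:

* clean (homoplasy-free) alignments evolved on a known tree;
* binary presence/absence marker matrices for several populations with
  *mosaic* hybrid individuals — every individual marker occurs in some
  parental population but the hybrid's marker combination occurs nowhere
  else, the fingerprint of reticulate ancestry in dominant markers;
* per-locus gene trees derived from one species tree by random rooted SPR
  moves (each move is one planted reticulation) with leaf dropout emulating
  loci sequenced for different accession subsets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .io import MarkerMatrix, SeqAlignment, TaxonSet
from .trees import Node, PhyloTree, TreeError


@dataclass
class PlantedTruth:
    species_tree: PhyloTree | None = None
    planted_splits: list = field(default_factory=list)
    hybrids: dict[str, tuple[str, str]] = field(default_factory=dict)
    populations: dict[str, list[str]] = field(default_factory=dict)
    locus_trees: list[PhyloTree] = field(default_factory=list)
    hybridizations_per_locus: int = 0
    mutated_edges: list[frozenset[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignments on a tree


def gen_alignment_on_tree(tree: PhyloTree, L: int, subst_rate: float = 1.0,
                          seed: int = 0, distinct_sites: bool = False
                          ) -> tuple[SeqAlignment, PlantedTruth]:
    """Infinite-sites alignment: each site mutates at most once.

    A site mutates with probability ``min(1, subst_rate)`` and the mutation
    falls on an edge with probability proportional to its length (uniform if
    lengths are absent).  Every polymorphic column therefore matches a tree
    split exactly — no homoplasy.  With ``distinct_sites`` each edge is used
    at most once and L may not exceed the edge count.
    """
    rng = random.Random(seed)
    nodes = [n for n in tree.root.walk() if n is not tree.root]
    weights = [n.length if n.length is not None else 1.0 for n in nodes]
    leaves = tree.leaf_labels()

    def clade(node: Node) -> frozenset[str]:
        return frozenset(n.label for n in node.walk() if n.is_leaf)

    if distinct_sites and L > len(nodes):
        raise ValueError(f"{L} distinct sites requested but only "
                         f"{len(nodes)} edges available")

    available = list(range(len(nodes)))
    columns: list[frozenset[str]] = []
    mutated: list[frozenset[str]] = []
    for _ in range(L):
        if rng.random() >= min(1.0, subst_rate):
            columns.append(frozenset())
            continue
        if distinct_sites:
            i = rng.choices(available, weights=[weights[j] for j in available])[0]
            available.remove(i)
        else:
            i = rng.choices(range(len(nodes)), weights=weights)[0]
        derived = clade(nodes[i])
        columns.append(derived)
        if 0 < len(derived) < len(leaves):
            mutated.append(derived)

    rows = {l: [] for l in leaves}
    for derived in columns:
        for l in leaves:
            rows[l].append("C" if l in derived else "A")
    aln = SeqAlignment(TaxonSet(leaves), ["".join(rows[l]) for l in leaves],
                       locus_name="synthetic")
    truth = PlantedTruth(species_tree=tree, mutated_edges=mutated)
    return aln, truth


# ---------------------------------------------------------------------------
# hybrid marker matrices


def gen_hybrid_markers(n_per_pop: list[int], n_markers: int,
                       hybrid_spec: list[tuple[int, int, float]] | None = None,
                       seed: int = 0) -> tuple[MarkerMatrix, PlantedTruth]:
    """Population-diagnostic marker blocks with planted mosaic hybrids.

    Markers are dealt round-robin to populations; a marker diagnostic for
    population p is present in all its members and absent elsewhere.  Each
    ``(parentA, parentB, mixture)`` hybrid carries, marker by marker, parent
    A's call with probability ``mixture`` and parent B's otherwise, with at
    least one diagnostic marker of each parent forced — so every individual
    marker exists in a parent population while the hybrid's *combination*
    exists only in the hybrid.
    """
    if len(n_per_pop) < 2:
        raise ValueError("need at least 2 populations")
    rng = random.Random(seed)
    P = len(n_per_pop)
    labels: list[str] = []
    groups: dict[str, dict[str, str]] = {}
    populations: dict[str, list[str]] = {}
    for p, count in enumerate(n_per_pop):
        pop = f"pop{p + 1}"
        populations[pop] = []
        for i in range(count):
            lab = f"p{p + 1}_{i + 1:02d}"
            labels.append(lab)
            groups[lab] = {"category": pop, "region": ""}
            populations[pop].append(lab)

    marker_owner = [m % P for m in range(n_markers)]
    marker_names = [f"M{m + 1:02d}" for m in range(n_markers)]
    calls = {}
    for p in range(P):
        for lab in populations[f"pop{p + 1}"]:
            calls[lab] = [1 if marker_owner[m] == p else 0
                          for m in range(n_markers)]

    truth = PlantedTruth(populations=populations)
    for p, pop in enumerate(populations):
        members = frozenset(populations[pop])
        rest = frozenset(labels) - members
        if members and rest:
            truth.planted_splits.append((members, rest))

    hybrids: list[str] = []
    for hidx, (pa, pb, mix) in enumerate(hybrid_spec or []):
        lab = f"hyb{hidx + 1}"
        hybrids.append(lab)
        groups[lab] = {"category": "hybrid", "region": ""}
        a = [1 if marker_owner[m] == pa else 0 for m in range(n_markers)]
        b = [1 if marker_owner[m] == pb else 0 for m in range(n_markers)]
        row = [a[m] if rng.random() < mix else b[m] for m in range(n_markers)]
        # force at least one diagnostic marker from each parent
        for parent, vec in ((pa, a), (pb, b)):
            own = [m for m in range(n_markers) if marker_owner[m] == parent]
            if own and not any(row[m] == 1 and vec[m] == 1 for m in own):
                row[own[0]] = 1
        calls[lab] = row
        truth.hybrids[lab] = (f"pop{pa + 1}", f"pop{pb + 1}")

    all_labels = labels + hybrids
    mm = MarkerMatrix(TaxonSet(all_labels, groups), marker_names,
                      [calls[l] for l in all_labels])
    return mm, truth


# ---------------------------------------------------------------------------
# discordant gene trees


def _detach(tree: PhyloTree, node: Node) -> PhyloTree:
    """Remove ``node``'s subtree, suppressing the emptied parent."""

    def prune(cur: Node) -> Node | None:
        if cur is node:
            return None
        if cur.is_leaf:
            return cur
        kids = [k for k in (prune(c) for c in cur.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1 and cur is not tree.root:
            return kids[0]
        new = Node(cur.label, cur.length, cur.support)
        new.children = kids
        return new

    root = prune(tree.root)
    if root is not None and len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
    return PhyloTree(root, rooted=True)


def _attach_above(tree: PhyloTree, target: Node, sub: Node) -> PhyloTree:
    """Insert ``sub`` as sibling of ``target`` via a new internal node."""

    def rebuild(cur: Node) -> Node:
        if cur is target:
            return Node(children=[cur, sub])
        if cur.is_leaf:
            return cur
        new = Node(cur.label, cur.length, cur.support)
        new.children = [rebuild(c) for c in cur.children]
        return new

    if tree.root is target:
        return PhyloTree(Node(children=[tree.root, sub]), rooted=True)
    return PhyloTree(rebuild(tree.root), rooted=True)


def rspr(tree: PhyloTree, rng: random.Random) -> PhyloTree:
    """One random rooted subtree-prune-regraft move (a planted reticulation)."""
    for _ in range(100):
        nodes = [n for n in tree.root.walk() if n is not tree.root]
        sub = nodes[rng.randrange(len(nodes))]
        sub_leaves = {n.label for n in sub.walk() if n.is_leaf}
        if len(sub_leaves) >= tree.n_leaves() - 1:
            continue
        pruned = _detach(tree, sub)
        targets = [n for n in pruned.root.walk()]
        target = targets[rng.randrange(len(targets))]
        moved = _attach_above(pruned, target, sub.copy())
        if not moved.same_topology(tree):
            return moved
    raise TreeError("could not find a topology-changing SPR move")


def gen_discordant_trees(species_tree: PhyloTree, n_loci: int,
                         hybrid_edges: int = 1, taxon_dropout: float = 0.0,
                         seed: int = 0) -> tuple[list[PhyloTree], PlantedTruth]:
    """Per-locus trees: the species tree plus random rSPR moves and dropout.

    Each locus tree receives ``hybrid_edges`` random SPR moves (0 keeps the
    species tree) and then loses each leaf independently with probability
    ``taxon_dropout`` (at least 3 leaves are always kept), emulating partial
    trees from loci sequenced in different accession subsets.
    """
    rng = random.Random(seed)
    trees: list[PhyloTree] = []
    for _ in range(n_loci):
        t = species_tree.copy()
        for _ in range(hybrid_edges):
            t = rspr(t, rng)
        if taxon_dropout > 0:
            leaves = t.leaf_labels()
            keep = [l for l in leaves if rng.random() >= taxon_dropout]
            if len(keep) < 3:
                keep = rng.sample(leaves, 3)
            t = t.restrict(set(keep))
        trees.append(t)
    truth = PlantedTruth(species_tree=species_tree, locus_trees=trees,
                         hybridizations_per_locus=hybrid_edges)
    return trees, truth
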