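"""Lightweight phylogenetic trees.

Trees here are plain node structures over string leaf labels.  They may be
rooted or unrooted (an unrooted tree is stored as a rooted structure whose
root is an arbitrary internal vertex; the ``rooted`` flag records whether the
root placement carries meaning).  Multifurcations are allowed everywhere.
Leaf sets of different trees may differ: a tree over a subset of a global
taxon set is a *partial* tree.

Newick text handling lives in :mod:`emmernet.io`; this module is purely
structural.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "Node":
        n = Node(self.label, self.length, self.support)
        n.children = [c.copy() for c in self.children]
        return n


@dataclass
class PhyloTree:
    """A rooted or unrooted tree over a set of leaf labels.

    Invariants: leaf labels are unique; internal vertices have at least two
    children (a degree-2 root is tolerated on rooted trees).
    """

    root: Node
    rooted: bool = False

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels in tree")

    # -- basic queries ---------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.walk() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    # -- clusters & splits ----------------------------------------------

    def clusters(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Leaf sets below each internal edge (rooted reading).

        For a rooted tree these are the clades.  The full leaf set and, unless
        ``include_trivial``, singletons are omitted.
        """
        all_leaves = self.taxa
        out: set[frozenset[str]] = set()

        def below(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            leaves = frozenset().union(*(below(c) for c in node.children))
            if leaves != all_leaves and (include_trivial or len(leaves) > 1):
                out.add(leaves)
            return leaves

        for child in self.root.children:
            below(child)
        return out

    # -- editing ---------------------------------------------------------

    def restrict(self, keep: set[str]) -> "PhyloTree":
        """Restriction to a leaf subset, suppressing degree-2 vertices."""
        keep = set(keep) & self.taxa
        if not keep:
            raise TreeError("restriction to empty leaf set")

        def prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node.copy() if node.label in keep else None
            kids = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                # suppress: pass the single survivor up, accumulating length
                child = kids[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            new = Node(node.label, node.length, node.support)
            new.children = kids
            return new

        root = prune(self.root)
        if root is None:
            raise TreeError("restriction removed all leaves")
        if root.is_leaf:
            # single surviving leaf: wrap so the result is still a tree
            wrap = Node(children=[root])
            return PhyloTree(wrap, self.rooted)
        if not self.rooted and len(root.children) == 2:
            # an unrooted tree must not keep an artificial degree-2 root
            a, b = root.children
            if b.is_leaf and not a.is_leaf:
                a, b = b, a
            if not b.is_leaf:
                merged = Node(root.label, root.length, root.support)
                merged.children = [a] + b.children
                root = merged
        return PhyloTree(root, self.rooted)

    # -- equality of shape ----------------------------------------------

    def topology_key(self) -> tuple:
        """Canonical hashable form of the topology (labels only).

        Rooted trees compare as rooted; unrooted trees compare via their
        nontrivial split sets (plus the leaf set).
        """
        if self.rooted:
            def key(node: Node):
                if node.is_leaf:
                    return node.label
                return tuple(sorted((key(c) for c in node.children), key=repr))
            return ("rooted", key(self.root))
        splits = frozenset(
            frozenset((cl, self.taxa - cl)) for cl in self.clusters()
            if 1 < len(cl) < len(self.taxa) - 1
        )
        return ("unrooted", self.taxa, splits)

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.topology_key() == other.topology_key()


# ---------------------------------------------------------------------------
# construction helpers


def tree_from_clusters(taxa: set[str], clusters: set[frozenset[str]],
                       rooted: bool = True,
                       support: dict[frozenset[str], float] | None = None) -> PhyloTree:
    """Build a tree whose clades are exactly a laminar family of clusters.

    ``clusters`` must be pairwise nested-or-disjoint proper subsets of
    ``taxa``; singletons are implied and may be omitted.
    """
    taxa = frozenset(taxa)
    clusters = {frozenset(c) for c in clusters if 1 < len(c) < len(taxa)}
    for a, b in itertools.combinations(clusters, 2):
        if a & b and not (a <= b or b <= a):
            raise TreeError("cluster family is not laminar")

    def build(leafset: frozenset[str], available: set[frozenset[str]]) -> Node:
        maximal = [c for c in available
                   if c < leafset and not any(c < d < leafset for d in available)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        node = Node()
        if leafset in (support or {}):
            node.support = support[leafset]
        for c in sorted(maximal, key=lambda s: sorted(s)):
            node.children.append(build(c, {d for d in available if d < c}))
        for leaf in sorted(leafset - covered):
            node.children.append(Node(label=leaf))
        return node

    return PhyloTree(build(taxa, clusters), rooted)


def random_binary_tree(labels: list[str], rng) -> PhyloTree:
    """Uniform-ish random rooted binary tree by sequential random attachment."""
    if len(labels) < 2:
        raise TreeError("need at least 2 labels")
    order = list(labels)
    rng.shuffle(order)
    root = Node(children=[Node(label=order[0]), Node(label=order[1])])
    for lab in order[2:]:
        # pick a random edge = a random non-root node, insert above it
        nodes = [n for n in root.walk() if n is not root]
        target = nodes[rng.randrange(len(nodes))]
        parent = next(p for p in root.walk() if target in p.children)
        joint = Node(children=[target, Node(label=lab)])
        parent.children[parent.children.index(target)] = joint
    return PhyloTree(root, rooted=True)
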