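"""Pairwise rooted-tree conflict and minimum hybridization numbers.

Two rooted gene trees that cannot be reconciled by a single history imply
hybridization (or other reticulate) events; the minimum number needed is
one less than the size of a maximum *acyclic agreement forest* (MAAF) of
the pair.  This module detects conflicting pairs and computes the exact
hybridization number on desk-scale instances by iterative deepening over
edge cuts, with an independent brute-force partition search available for
verification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .trees import Node, PhyloTree, TreeError


class HybridError(ValueError):
    pass


# ---------------------------------------------------------------------------
# restriction and conflict


def restrict_pair(t1: PhyloTree, t2: PhyloTree) -> tuple[PhyloTree, PhyloTree]:
    """Restrict both trees to their common leaves (degree-2 vertices suppressed)."""
    common = t1.taxa & t2.taxa
    if len(common) < 2:
        raise HybridError("trees share fewer than 2 taxa")
    return t1.restrict(common), t2.restrict(common)


def _clusters_incompatible(a: frozenset[str], b: frozenset[str]) -> bool:
    """Rooted incompatibility: overlapping but neither nested."""
    return bool(a & b) and not (a <= b or b <= a)


def trees_conflict(t1: PhyloTree, t2: PhyloTree) -> bool:
    """True iff some cluster of one tree is incompatible with one of the other.

    Trees are compared on their common taxa.
    """
    if t1.taxa != t2.taxa:
        t1, t2 = restrict_pair(t1, t2)
    c1 = t1.clusters()
    c2 = t2.clusters()
    return any(_clusters_incompatible(a, b) for a in c1 for b in c2)


# ---------------------------------------------------------------------------
# indexed rooted tree for forest search

_RHO = "ρ"  # the artificial root leaf


class _Indexed:
    """Array view of a rooted tree with an extra root leaf attached."""

    def __init__(self, tree: PhyloTree):
        rho = Node(label=_RHO)
        top = Node(children=[tree.root.copy(), rho])
        self.parent: list[int | None] = []
        self.children: list[list[int]] = []
        self.label: list[str | None] = []
        self.leafset: list[frozenset[str]] = []

        def add(node: Node, parent: int | None) -> int:
            idx = len(self.parent)
            self.parent.append(parent)
            self.children.append([])
            self.label.append(node.label)
            self.leafset.append(frozenset())
            for c in node.children:
                ci = add(c, idx)
                self.children[idx].append(ci)
            if node.is_leaf:
                self.leafset[idx] = frozenset([node.label])
            else:
                self.leafset[idx] = frozenset().union(
                    *(self.leafset[c] for c in self.children[idx]))
            return idx

        add(top, None)
        self.n = len(self.parent)
        self.leaf_node = {self.label[i]: i for i in range(self.n)
                          if not self.children[i]}
        # edges identified by their child node; every non-root node has one
        self.edges = [i for i in range(self.n) if self.parent[i] is not None]

    def is_ancestor(self, u: int, v: int) -> bool:
        """Strict ancestor test."""
        while self.parent[v] is not None:
            v = self.parent[v]
            if v == u:
                return True
        return False

    def lca_of(self, leaves: frozenset[str]) -> int:
        cur = self.leaf_node[next(iter(leaves))]
        while not leaves <= self.leafset[cur]:
            cur = self.parent[cur]
        return cur

    def spanning_vertices(self, leaves: frozenset[str]) -> frozenset[int]:
        top = self.lca_of(leaves)
        verts = {top}
        for l in leaves:
            v = self.leaf_node[l]
            while v != top:
                verts.add(v)
                v = self.parent[v]
        return frozenset(verts)

    def restricted_clusters(self, leaves: frozenset[str]) -> frozenset[frozenset[str]]:
        """Cluster family of the restriction to ``leaves``."""
        verts = self.spanning_vertices(leaves)
        fam = {self.leafset[v] & leaves for v in verts}
        fam.discard(frozenset())
        return frozenset(fam)


def _blocks_from_cuts(idx: _Indexed, cuts: frozenset[int]) -> list[frozenset[str]]:
    """Leaf blocks of the components after deleting the cut edges."""
    comp_root: dict[int, int] = {}

    def root_of(v: int) -> int:
        path = []
        while v not in comp_root:
            path.append(v)
            if v in cuts or idx.parent[v] is None:
                comp_root.update({p: v for p in path})
                return v
            v = idx.parent[v]
        r = comp_root[v]
        comp_root.update({p: r for p in path})
        return r

    blocks: dict[int, set[str]] = {}
    for label, node in idx.leaf_node.items():
        blocks.setdefault(root_of(node), set()).add(label)
    return [frozenset(b) for b in blocks.values()]


def _is_agreement_forest(i1: _Indexed, i2: _Indexed,
                         blocks: list[frozenset[str]],
                         check_t1: bool = False) -> bool:
    spans2 = []
    for b in blocks:
        if i1.restricted_clusters(b) != i2.restricted_clusters(b):
            return False
        spans2.append(i2.spanning_vertices(b))
    for a, b in itertools.combinations(spans2, 2):
        if a & b:
            return False
    if check_t1:
        spans1 = [i1.spanning_vertices(b) for b in blocks]
        for a, b in itertools.combinations(spans1, 2):
            if a & b:
                return False
    return True


def _is_acyclic(i1: _Indexed, i2: _Indexed, blocks: list[frozenset[str]]) -> bool:
    roots1 = [i1.lca_of(b) for b in blocks]
    roots2 = [i2.lca_of(b) for b in blocks]
    k = len(blocks)
    succ: list[set[int]] = [set() for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if i1.is_ancestor(roots1[i], roots1[j]) or i2.is_ancestor(roots2[i], roots2[j]):
                succ[i].add(j)
    # DFS cycle check
    state = [0] * k

    def dfs(u: int) -> bool:
        state[u] = 1
        for v in succ[u]:
            if state[v] == 1 or (state[v] == 0 and dfs(v)):
                return True
        state[u] = 2
        return False

    return not any(state[u] == 0 and dfs(u) for u in range(k))


# ---------------------------------------------------------------------------
# polytomy resolution (soft multifurcations)


def _resolutions(node: Node, max_degree: int) -> list[Node]:
    """All binary resolutions of a subtree; polytomies above ``max_degree``
    are kept as-is (hard) with a warning."""
    if node.is_leaf:
        return [Node(node.label)]
    child_options = [_resolutions(c, max_degree) for c in node.children]
    out = []
    for combo in itertools.product(*child_options):
        subs = list(combo)
        if len(subs) <= 2 or len(subs) > max_degree:
            if len(subs) > max_degree:
                warnings.warn("polytomy above resolution cap treated as hard")
            out.append(Node(children=subs))
        else:
            out.extend(_binary_joins(subs))
    return out


def _binary_joins(subs: list[Node]) -> list[Node]:
    if len(subs) == 2:
        return [Node(children=list(subs))]
    out = []
    first, rest = subs[0], subs[1:]
    for r in _binary_joins(rest) if len(rest) > 1 else [rest[0]]:
        # insert `first` on every edge of the resolved remainder r,
        # or join at the top
        positions = _insert_everywhere(r, first)
        out.extend(positions)
    return out


def _insert_everywhere(tree: Node, sub: Node) -> list[Node]:
    out = [Node(children=[_copy(tree), _copy(sub)])]

    def recurse(node: Node, path: list[int]) -> None:
        for i, child in enumerate(node.children):
            new = _copy(tree)
            target = new
            for p in path:
                target = target.children[p]
            target.children[i] = Node(children=[target.children[i], _copy(sub)])
            out.append(new)
            recurse(child, path + [i])

    recurse(tree, [])
    return out


def _copy(node: Node) -> Node:
    return node.copy()


# ---------------------------------------------------------------------------
# public API


def min_hybridization(t1: PhyloTree, t2: PhyloTree, cap: int = 10,
                      exact_limit: int = 12, polytomy_degree_cap: int = 5) -> int:
    """Exact minimum hybridization number of a rooted tree pair.

    Equals (size of a maximum acyclic agreement forest) - 1, found by
    iterative deepening over edges cut in the first tree.  Soft polytomies
    are handled by minimising over binary resolutions up to
    ``polytomy_degree_cap``.  Returns ``cap + 1`` if the number exceeds
    ``cap``; refuses instances above ``exact_limit`` common taxa.
    """
    if t1.taxa != t2.taxa:
        t1, t2 = restrict_pair(t1, t2)
    n = len(t1.taxa)
    if n > exact_limit:
        raise HybridError(
            f"{n} common taxa exceeds the exact limit ({exact_limit}); subsample")
    if not trees_conflict(t1, t2):
        return 0

    res1 = [PhyloTree(r, rooted=True)
            for r in _resolutions(t1.root, polytomy_degree_cap)]
    res2 = [PhyloTree(r, rooted=True)
            for r in _resolutions(t2.root, polytomy_degree_cap)]
    best = cap + 1
    for r1 in res1:
        for r2 in res2:
            h = _min_hyb_binary(r1, r2, min(cap, best - 1))
            best = min(best, h)
            if best == 1:
                return 1
    return best


def _min_hyb_binary(t1: PhyloTree, t2: PhyloTree, cap: int) -> int:
    i1, i2 = _Indexed(t1), _Indexed(t2)
    for d in range(1, cap + 1):
        found = None
        for cuts in itertools.combinations(i1.edges, d):
            blocks = _blocks_from_cuts(i1, frozenset(cuts))
            if len(blocks) != d + 1:
                continue
            if _is_agreement_forest(i1, i2, blocks) and _is_acyclic(i1, i2, blocks):
                h = len(blocks) - 1
                found = h if found is None else min(found, h)
        if found is not None:
            return found
    return cap + 1


def min_hybridization_bruteforce(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent oracle: exhaustive search over all leaf-set partitions.

    Checks every set partition of the leaves plus the artificial root for
    being an acyclic agreement forest of both trees, minimising the
    component count.  Exponential; use only on small instances.
    """
    if t1.taxa != t2.taxa:
        t1, t2 = restrict_pair(t1, t2)
    i1, i2 = _Indexed(t1), _Indexed(t2)
    universe = sorted(t1.taxa | {_RHO})

    best = len(universe)
    for part in _set_partitions(universe):
        blocks = [frozenset(b) for b in part]
        if len(blocks) - 1 >= best:
            continue
        if (_is_agreement_forest(i1, i2, blocks, check_t1=True)
                and _is_acyclic(i1, i2, blocks)):
            best = len(blocks) - 1
    return best


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


# ---------------------------------------------------------------------------
# pairwise report


@dataclass
class PairwiseConflictReport:
    n_pairs: int
    n_conflicting: int
    hybridizations: dict[tuple[int, int], int] = field(default_factory=dict)
    mean_hybridizations: float | None = None

    def as_rows(self) -> list[dict]:
        return [{"tree_i": i, "tree_j": j, "hybridizations": h}
                for (i, j), h in sorted(self.hybridizations.items())]


def pairwise_report(trees: list[PhyloTree], cap: int = 10,
                    exact_limit: int = 12) -> PairwiseConflictReport:
    """Examine all unordered tree pairs; hybridization numbers for the
    conflicting ones and their mean (1 d.p. convention in displays).

    Pairs sharing fewer than two taxa cannot conflict and count as
    non-conflicting.
    """
    if len(trees) < 2:
        raise HybridError("need at least 2 trees")
    report = PairwiseConflictReport(n_pairs=0, n_conflicting=0)
    for i, j in itertools.combinations(range(len(trees)), 2):
        report.n_pairs += 1
        common = trees[i].taxa & trees[j].taxa
        if len(common) < 2:
            continue
        r1, r2 = restrict_pair(trees[i], trees[j])
        if trees_conflict(r1, r2):
            report.n_conflicting += 1
            report.hybridizations[(i, j)] = min_hybridization(
                r1, r2, cap=cap, exact_limit=exact_limit)
    if report.n_conflicting:
        report.mean_hybridizations = (
            sum(report.hybridizations.values()) / report.n_conflicting)
    return report
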