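"""Maximum parsimony: scoring, search, consensus, bootstrap, incongruence.

Scoring uses Fitch's downpass on binary trees and the unit-cost Sankoff
recursion on multifurcating ones (the two agree on binary trees).  Gaps and
ambiguity codes are wildcards (full state set) by default; a 5-state mode
treating the gap as a real character is available via ``gap_as_state``.

The search is exact (all unrooted topologies) up to ``exhaustive_limit``
taxa and otherwise a jumbled stepwise-addition + NNI hill-climb heuristic,
mirroring how MP trees are found in practice for matrices of this size.

The incongruence diagnostic compares the MP score of a concatenated matrix
with the sum of per-locus MP scores: equality means the loci agree on one
tree; a ratio above 1 quantifies conflict among gene histories.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .io import SeqAlignment
from .trees import Node, PhyloTree, TreeError, tree_from_clusters

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_GAP_BIT = 16


class ParsimonyError(ValueError):
    pass


@dataclass
class ScoredTree:
    tree: PhyloTree
    score: int


@dataclass
class ConsensusTree:
    """A consensus topology with per-cluster support percentages."""
    tree: PhyloTree
    supports: dict[frozenset[str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# encoding


def _symbol_mask(sym: str, gap_as_state: bool) -> int:
    if sym in _STATE_BITS:
        return _STATE_BITS[sym]
    if sym == "-" and gap_as_state:
        return _GAP_BIT
    # N, ?, ambiguity codes, and (by default) gaps: wildcard
    return 31 if gap_as_state else 15


def _encode_columns(aln: SeqAlignment, labels: list[str],
                    gap_as_state: bool) -> list[tuple[tuple[int, ...], int]]:
    """Compress columns to unique leaf-mask patterns with multiplicities."""
    rows = {l: aln.row(l) for l in labels}
    patterns: dict[tuple[int, ...], int] = {}
    for i in range(aln.n_columns):
        pat = tuple(_symbol_mask(rows[l][i], gap_as_state) for l in labels)
        patterns[pat] = patterns.get(pat, 0) + 1
    return list(patterns.items())


# ---------------------------------------------------------------------------
# scoring a given (possibly multifurcating) tree


def fitch_score(tree: PhyloTree, aln: SeqAlignment, gap_as_state: bool = False) -> int:
    """Minimum number of character changes of ``aln`` on ``tree``.

    Unit-cost Sankoff recursion: exact on multifurcations, equal to Fitch on
    binary trees, and invariant under re-rooting.  Missing symbols are
    wildcards.  Leaves of the tree must all carry sequences.
    """
    labels = tree.leaf_labels()
    missing = set(labels) - set(aln.taxa.labels)
    if missing:
        raise ParsimonyError(f"tree leaves without sequences: {sorted(missing)}")
    n_states = 5 if gap_as_state else 4
    leaf_index = {l: i for i, l in enumerate(labels)}
    total = 0
    for pat, weight in _encode_columns(aln, labels, gap_as_state):

        def cost_vector(node: Node) -> list[int]:
            if node.is_leaf:
                mask = pat[leaf_index[node.label]]
                return [0 if mask >> s & 1 else 1 for s in range(n_states)]
            vec = [0] * n_states
            for child in node.children:
                cv = cost_vector(child)
                m = min(cv)
                for s in range(n_states):
                    vec[s] += min(cv[s], m + 1)
            return vec

        total += weight * min(cost_vector(tree.root))
    return total


# ---------------------------------------------------------------------------
# adjacency machinery for search (binary unrooted trees)
#
# Trees are dicts node -> set(neighbours); leaves are 0..n-1 (indices into a
# label list), internal vertices are >= n.


def _star3(a: int, b: int, c: int, internal: int) -> dict[int, set[int]]:
    return {a: {internal}, b: {internal}, c: {internal},
            internal: {a, b, c}}


def _edges(adj: dict[int, set[int]]) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _insert_leaf(adj, leaf: int, edge: tuple[int, int], new_internal: int) -> None:
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[new_internal] = {u, v, leaf}
    adj[leaf] = {new_internal}


def _remove_leaf(adj, leaf: int, edge: tuple[int, int], internal: int) -> None:
    u, v = edge
    del adj[leaf]
    del adj[internal]
    adj[u].discard(internal)
    adj[v].discard(internal)
    adj[u].add(v)
    adj[v].add(u)


def _postorder(adj, root_leaf: int = 0) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents, rooted next to leaf 0."""
    start = next(iter(adj[root_leaf]))
    order: list[tuple[int, int]] = []
    stack = [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    order.reverse()
    return order


def _score_adj(adj, patterns, n_leaves: int) -> int:
    """Fitch score of a binary adjacency tree over compressed patterns.

    Works on partial trees (any subset of leaves present) so the stepwise
    insertion phase can score as it grows.
    """
    root_leaf = min(k for k in adj if k < n_leaves)
    order = _postorder(adj, root_leaf)
    total = 0
    for pat, weight in patterns:
        masks: dict[int, int] = {}
        cost = 0
        for node, parent in order:
            if node < n_leaves:
                masks[node] = pat[node]
            else:
                m = None
                for nb in adj[node]:
                    if nb == parent:
                        continue
                    cm = masks[nb]
                    if m is None:
                        m = cm
                    else:
                        inter = m & cm
                        if inter:
                            m = inter
                        else:
                            m = m | cm
                            cost += 1
                masks[node] = m
        root = order[-1][0]
        if not masks[root] & pat[root_leaf]:
            cost += 1
        total += weight * cost
    return total


def _adj_to_tree(adj, labels: list[str]) -> PhyloTree:
    n = len(labels)
    start = next(iter(adj[0]))

    def build(node: int, parent: int) -> Node:
        if node < n:
            return Node(label=labels[node])
        out = Node()
        out.children = [build(nb, node) for nb in sorted(adj[node]) if nb != parent]
        return out

    root = Node()
    root.children = [Node(label=labels[0])] + [
        build(nb, start) for nb in sorted(adj[start]) if nb != 0]
    return PhyloTree(root, rooted=False)


def _iter_topologies(n: int):
    """Yield (live, do-not-keep) adjacency dicts over all unrooted binary
    topologies on leaves 0..n-1 by recursive edge insertion."""
    adj = _star3(0, 1, 2, n)

    def recurse(k: int, next_internal: int):
        if k == n:
            yield adj
            return
        for edge in _edges(adj):
            _insert_leaf(adj, k, edge, next_internal)
            yield from recurse(k + 1, next_internal + 1)
            _remove_leaf(adj, k, edge, next_internal)

    yield from recurse(3, n + 1)


def _nni_neighbours(adj, n_leaves: int):
    """Yield adjacency copies one NNI away (around internal edges)."""
    for u, v in _edges(adj):
        if u < n_leaves or v < n_leaves:
            continue
        a, b = [x for x in adj[u] if x != v]
        c, d = [x for x in adj[v] if x != u]
        for x, y in ((b, c), (b, d)):
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(x); new[x].discard(u)
            new[v].discard(y); new[y].discard(v)
            new[u].add(y); new[y].add(u)
            new[v].add(x); new[x].add(v)
            yield new


def mp_search(aln: SeqAlignment, n_jumbles: int = 10, seed: int = 0,
              exhaustive_limit: int = 9, gap_as_state: bool = False) -> list[ScoredTree]:
    """Search for most parsimonious unrooted trees.

    Exact enumeration up to ``exhaustive_limit`` taxa, otherwise
    ``n_jumbles`` random-addition-order stepwise insertions each refined by
    NNI hill climbing.  All distinct best-scoring topologies found are
    returned, canonicalised and sorted for reproducibility.
    """
    labels = list(aln.taxa.labels)
    n = len(labels)
    if n < 3:
        raise ParsimonyError("parsimony search needs at least 3 taxa")
    patterns = _encode_columns(aln, labels, gap_as_state)

    best_score: int | None = None
    best: dict = {}  # topology_key -> PhyloTree

    def consider(adj, score: int) -> None:
        nonlocal best_score
        if best_score is None or score < best_score:
            best_score = score
            best.clear()
        if score == best_score:
            t = _adj_to_tree(adj, labels)
            best.setdefault(t.topology_key(), t)

    if n == 3:
        adj = _star3(0, 1, 2, 3)
        consider(adj, _score_adj(adj, patterns, n))
    elif n <= exhaustive_limit:
        for adj in _iter_topologies(n):
            consider(adj, _score_adj(adj, patterns, n))
    else:
        rng = random.Random(seed)
        for _ in range(max(1, n_jumbles)):
            order = list(range(n))
            rng.shuffle(order)
            # relabelling trick: build over permuted leaf ids directly
            adj = _star3(order[0], order[1], order[2], n)
            next_internal = n + 1
            for leaf in order[3:]:
                best_edge, best_s = None, None
                for edge in _edges(adj):
                    _insert_leaf(adj, leaf, edge, next_internal)
                    s = _score_adj(adj, patterns, n)
                    _remove_leaf(adj, leaf, edge, next_internal)
                    if best_s is None or s < best_s:
                        best_edge, best_s = edge, s
                _insert_leaf(adj, leaf, best_edge, next_internal)
                next_internal += 1
            score = _score_adj(adj, patterns, n)
            improved = True
            while improved:
                improved = False
                for cand in _nni_neighbours(adj, n):
                    s = _score_adj(cand, patterns, n)
                    if s < score:
                        adj, score = cand, s
                        improved = True
                        break
            consider(adj, score)

    trees = [best[k] for k in sorted(best, key=repr)]
    return [ScoredTree(t, best_score) for t in trees]


# ---------------------------------------------------------------------------
# consensus


def _check_same_leaves(trees: list[PhyloTree]) -> frozenset[str]:
    leaf_sets = {t.taxa for t in trees}
    if len(leaf_sets) != 1:
        raise TreeError("consensus requires identical leaf sets; restrict first")
    return next(iter(leaf_sets))


def _unrooted_clusters(tree: PhyloTree, anchor: str) -> set[frozenset[str]]:
    """Nontrivial splits as clusters on the side away from ``anchor``."""
    taxa = tree.taxa
    out = set()
    for cl in tree.clusters():
        rest = taxa - cl
        if len(cl) < 2 or len(rest) < 2:
            continue
        out.add(rest if anchor in cl else cl)
    return out


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the clusters present in every input tree."""
    taxa = _check_same_leaves(trees)
    anchor = min(taxa)
    common = set.intersection(*(_unrooted_clusters(t, anchor) for t in trees))
    return tree_from_clusters(set(taxa), common, rooted=False)


def majority_consensus(trees: list[PhyloTree],
                       threshold_pct: float = 50.0) -> ConsensusTree:
    """Clusters occurring in more than ``threshold_pct`` percent of trees."""
    taxa = _check_same_leaves(trees)
    anchor = min(taxa)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for cl in _unrooted_clusters(t, anchor):
            counts[cl] = counts.get(cl, 0) + 1
    total = len(trees)
    kept: dict[frozenset[str], float] = {}
    # descending frequency; skip anything incompatible with what is kept
    # (only possible below the 50% threshold)
    for cl, c in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        pct = 100.0 * c / total
        if pct <= threshold_pct:
            continue
        if all(_clusters_compatible(cl, other) for other in kept):
            kept[cl] = pct
    tree = tree_from_clusters(set(taxa), set(kept), rooted=False, support=kept)
    return ConsensusTree(tree, kept)


def _clusters_compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return not (a & b) or a <= b or b <= a


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(aln: SeqAlignment, replicates: int = 100, seed: int = 0,
                      n_jumbles: int = 2, exhaustive_limit: int = 9) -> ConsensusTree:
    """Column-resampling bootstrap of the MP analysis.

    Each replicate resamples columns with replacement to the original
    length, runs :func:`mp_search`, and contributes its first canonical best
    tree; supports are percentages over replicates and the returned topology
    is the majority-rule consensus of the replicate trees.
    """
    if replicates < 1:
        raise ParsimonyError("need at least one bootstrap replicate")
    rng = random.Random(seed)
    L = aln.n_columns
    reps = []
    for _ in range(replicates):
        idx = [rng.randrange(L) for _ in range(L)]
        sub = aln.select_columns(idx)
        found = mp_search(sub, n_jumbles=n_jumbles,
                          seed=rng.randrange(2 ** 30),
                          exhaustive_limit=exhaustive_limit)
        reps.append(found[0].tree)
    return majority_consensus(reps)


# ---------------------------------------------------------------------------
# incongruence


def incongruence_ratio(concat_score: int, locus_scores: list[int]) -> float:
    """Concatenated MP score over the sum of per-locus MP scores.

    Always >= 1 when scores are exact on the same taxon universe; values
    above 1 indicate that no single tree fits all loci (gene-tree conflict).
    """
    total = sum(locus_scores)
    if total == 0:
        raise ParsimonyError("sum of locus scores is zero; ratio undefined")
    return concat_score / total
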