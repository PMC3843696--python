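"""Median-joining haplotype networks.

Distinct sequences collapse to haplotypes weighted by the number of
accessions carrying them; the network connects them through minimum-spanning
edges plus inferred *median vectors* (unsampled intermediate haplotypes,
Steiner points of the Hamming metric).  This is the classic construction for
intraspecific allele data where ancestral haplotypes persist alongside their
descendants and a bifurcating tree is the wrong picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import SeqAlignment


class HaploError(ValueError):
    pass


@dataclass
class Haplotype:
    id: str
    states: tuple[str, ...]
    multiplicity: int = 0
    group_counts: dict[str, int] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)

    @property
    def observed(self) -> bool:
        return self.multiplicity > 0


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    edges: list[tuple[int, int, int]]  # (node index, node index, mutations)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for i, j, d in self.edges:
            g.add_edge(i, j, weight=d)
        return g

    @property
    def connected(self) -> bool:
        return nx.is_connected(self.graph())

    def steiner_cost(self) -> int:
        """Total mutation count of a spanning tree of the node set."""
        mst = nx.minimum_spanning_tree(self.graph())
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def hamming(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


# ---------------------------------------------------------------------------


def collapse_haplotypes(aln: SeqAlignment) -> list[Haplotype]:
    """Merge identical rows into haplotypes with multiplicities and group counts."""
    order: list[tuple[str, ...]] = []
    by_states: dict[tuple[str, ...], Haplotype] = {}
    for label, row in zip(aln.taxa.labels, aln.rows):
        states = tuple(row)
        if states not in by_states:
            by_states[states] = Haplotype(f"H{len(order) + 1}", states)
            order.append(states)
        h = by_states[states]
        h.multiplicity += 1
        h.members.append(label)
        cat = aln.taxa.category(label)
        if cat:
            h.group_counts[cat] = h.group_counts.get(cat, 0) + 1
    return [by_states[s] for s in order]


# ---------------------------------------------------------------------------
# minimum spanning network


def _minimax_distances(vectors: list[tuple[str, ...]]):
    """Pairwise Hamming and minimax-path (MST bottleneck) distances."""
    n = len(vectors)
    d = [[hamming(vectors[i], vectors[j]) for j in range(n)] for i in range(n)]
    mm = [row[:] for row in d]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                cand = max(mm[i][k], mm[k][j])
                if cand < mm[i][j]:
                    mm[i][j] = cand
    return d, mm


def _msn_edges(vectors: list[tuple[str, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u,v) belongs iff its Hamming distance is within ``epsilon`` of
    the bottleneck (minimax path) distance between u and v — for epsilon 0
    exactly the union of all minimum spanning trees.
    """
    d, mm = _minimax_distances(vectors)
    n = len(vectors)
    return [(i, j, d[i][j]) for i in range(n) for j in range(i + 1, n)
            if d[i][j] <= mm[i][j] + epsilon]


def minimum_spanning_network(haps: list[Haplotype], epsilon: int = 0) -> HaplotypeNetwork:
    if len(haps) < 2:
        raise HaploError("need at least 2 haplotypes")
    vectors = [h.states for h in haps]
    return HaplotypeNetwork(list(haps), _msn_edges(vectors, epsilon))


# ---------------------------------------------------------------------------
# median joining


def _mst_cost(vectors: list[tuple[str, ...]]) -> int:
    g = nx.Graph()
    g.add_nodes_from(range(len(vectors)))
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            g.add_edge(i, j, weight=hamming(vectors[i], vectors[j]))
    mst = nx.minimum_spanning_tree(g)
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def _majority_median(u, v, w) -> tuple[str, ...]:
    """Per-position majority state; three-way ties resolve to u's state."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b if a != b else a)
        elif a == b or a == c:
            out.append(a)
        else:
            out.append(a)
    return tuple(out)


def median_joining(haps: list[Haplotype], epsilon: int = 0,
                   max_iterations: int = 500) -> HaplotypeNetwork:
    """Median-joining network: minimum spanning network plus cost-reducing
    median vectors, iterated to a fixed point.

    Each round builds the epsilon-relaxed minimum spanning network, prunes
    unobserved vectors of degree <= 2 (obsolete medians), proposes the
    per-position majority median of every triple with at least two network
    edges among its pairs, and adds the median giving the largest strict
    reduction of total spanning cost (ties broken by lexicographic state
    vector).  Observed haplotypes are never removed.
    """
    if len(haps) < 2:
        raise HaploError("need at least 2 haplotypes")
    observed = [h.states for h in haps]
    vectors: list[tuple[str, ...]] = list(observed)
    observed_set = set(observed)

    for iteration in range(max_iterations):
        # prune obsolete medians
        while True:
            edges = _msn_edges(vectors, epsilon)
            degree = {i: 0 for i in range(len(vectors))}
            for i, j, _ in edges:
                degree[i] += 1
                degree[j] += 1
            drop = [i for i, v in enumerate(vectors)
                    if v not in observed_set and degree[i] <= 2]
            if not drop:
                break
            vectors = [v for i, v in enumerate(vectors) if i not in set(drop)]

        edges = _msn_edges(vectors, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(vectors))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)

        base_cost = _mst_cost(vectors)
        seen = set(vectors)
        best: tuple[int, tuple[str, ...]] | None = None
        candidates = set()
        for u in range(len(vectors)):
            for v in adj[u]:
                for w in adj[u] | adj[v]:
                    trip = tuple(sorted({u, v, w}))
                    if len(trip) == 3:
                        candidates.add(trip)
        for u, v, w in sorted(candidates):
            m = _majority_median(vectors[u], vectors[v], vectors[w])
            if m in seen:
                continue
            delta = _mst_cost(vectors + [m]) - base_cost
            if delta < 0 and (best is None or (delta, m) < best):
                best = (delta, m)
        if best is None:
            break
        vectors.append(best[1])
    else:
        raise HaploError("median joining did not converge within iteration cap")

    # assemble output: observed haplotypes keep identity; medians get ids
    nodes: list[Haplotype] = []
    by_states = {h.states: h for h in haps}
    mv = 0
    for v in vectors:
        if v in by_states:
            nodes.append(by_states[v])
        else:
            mv += 1
            nodes.append(Haplotype(f"mv{mv}", v, multiplicity=0))
    net = HaplotypeNetwork(nodes, _msn_edges([n.states for n in nodes], epsilon))
    return net
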