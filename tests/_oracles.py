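"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the library:
exhaustive enumeration, dynamic programming over the full state space, or
direct counting.  They are deliberately slow and simple.
"""

from __future__ import annotations

import heapq
import itertools


def steiner_cost_hypercube(terminals: list[tuple[str, ...]], L: int) -> int:
    """Minimum Steiner tree cost for binary vectors in the L-hypercube.

    Dreyfus–Wagner dynamic programme over all 2^L vertices; exact.
    """
    nodes = list(itertools.product("01", repeat=L))
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    terms = list(dict.fromkeys(terminals))
    t = len(terms)
    INF = 10 ** 9
    dp = [[INF] * n for _ in range(1 << t)]
    for i, term in enumerate(terms):
        dp[1 << i][idx[term]] = 0

    def neighbours(i: int):
        v = nodes[i]
        for p in range(L):
            w = v[:p] + ("1" if v[p] == "0" else "0",) + v[p + 1:]
            yield idx[w]

    for mask in range(1, 1 << t):
        d = dp[mask]
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                ds, do = dp[sub], dp[other]
                for v in range(n):
                    c = ds[v] + do[v]
                    if c < d[v]:
                        d[v] = c
            sub = (sub - 1) & mask
        pq = [(c, v) for v, c in enumerate(d) if c < INF]
        heapq.heapify(pq)
        while pq:
            c, v = heapq.heappop(pq)
            if c > d[v]:
                continue
            for w in neighbours(v):
                if c + 1 < d[w]:
                    d[w] = c + 1
                    heapq.heappush(pq, (c + 1, w))
    return min(dp[(1 << t) - 1])


def brute_force_fitch(tree, aln) -> int:
    """Minimum changes by enumerating every ancestral state assignment."""
    states = "ACGT"
    internal = [n for n in tree.root.walk() if not n.is_leaf]
    total = 0
    for col in range(aln.n_columns):
        colmap = {l: aln.row(l)[col] for l in aln.taxa.labels}
        best = 10 ** 9
        for assign in itertools.product(states, repeat=len(internal)):
            amap = dict(zip((id(n) for n in internal), assign))
            cost = 0

            def walk(node, parent_state):
                nonlocal cost
                if node.is_leaf:
                    st = colmap[node.label]
                    if st not in states:  # wildcard: free
                        st = parent_state
                else:
                    st = amap[id(node)]
                if parent_state is not None and st != parent_state and st is not None:
                    cost += 1
                for c in node.children:
                    walk(c, st)

            walk(tree.root, None)
            best = min(best, cost)
        total += best
    return total


def four_gametes_present(aln, i: int, j: int) -> bool:
    """Direct count: do all four gamete combinations occur in columns i, j?

    Only taxa with plain A/C/G/T (or gap, a real state for splits) in both
    columns are counted; columns are reduced to their binary major split
    first, so this matches binary-column split incompatibility.
    """
    coli, colj = aln.column(i), aln.column(j)
    good = set("ACGT-")
    pairs = {(a, b) for a, b in zip(coli, colj) if a in good and b in good}
    si = {a for a, _ in pairs}
    sj = {b for _, b in pairs}
    if len(si) != 2 or len(sj) != 2:
        raise ValueError("oracle needs binary columns")
    return len(pairs) == 4
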