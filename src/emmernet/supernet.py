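"""Filtered supernetworks from partial trees or raw splits.

Partial splits (from partial gene trees, or from single markers/columns) are
extended to the full taxon set by the Z-closure rule, counted against the
inputs that support them, filtered by a minimum-support threshold
(``minSupportingTrees``), and rendered as an abstract splits graph in which
every retained split is an edge class and mutually incompatible splits form
boxes — the visual signature of reticulate signal.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import networkx as nx

from .io import TaxonSet
from .splits import (Split, SplitSystem, are_compatible, restrict_split,
                     splits_from_tree)
from .trees import PhyloTree


class SupernetError(ValueError):
    pass


@dataclass
class FilterParams:
    """minSupportingTrees-style filtering threshold."""
    min_supporting: int = 0
    strict_greater: bool = True

    def keeps(self, count: int) -> bool:
        if self.strict_greater:
            return count > self.min_supporting
        return count >= self.min_supporting


@dataclass
class SplitsGraph:
    """Abstract splits graph: nodes are abstract, edges carry split ids."""
    graph: nx.MultiGraph
    taxon_node: dict[str, int]
    splits: list[Split]


# ---------------------------------------------------------------------------
# Z-closure


def _as_split_system(inp) -> SplitSystem:
    if isinstance(inp, PhyloTree):
        return splits_from_tree(inp)
    return inp


def _pair_key(s: tuple[frozenset, frozenset]) -> frozenset:
    return frozenset(s)


def zclosure(inputs: list, runs: int = 5, seed: int = 0) -> SplitSystem:
    """Extend partial splits to the full taxon set by Z-closure.

    The pairwise rule is swept in randomised order to a fixed point; splits
    still partial afterwards are completed by placing the absent taxa on
    ``side_b`` of their canonical form.  The union of distinct full splits
    over ``runs`` sweeps is returned (the closure depends on encounter
    order, so several randomised runs recover more of it).
    """
    systems = [_as_split_system(i) for i in inputs]
    all_taxa: set[str] = set()
    for sys in systems:
        all_taxa |= set(sys.taxa.labels)
    if not all_taxa:
        return SplitSystem(TaxonSet([]), [])
    base = [(s.side_a, s.side_b) for sys in systems for s in sys.splits]
    rng = random.Random(seed)
    full: dict = {}

    for _ in range(max(1, runs)):
        splits = list(base)
        changed = True
        while changed:
            changed = False
            order = list(range(len(splits)))
            rng.shuffle(order)
            for i, j in itertools.permutations(order, 2):
                s1, s2 = splits[i], splits[j]
                # the Z-rule: for orientations A1|B1, A2|B2 with A1 meeting
                # A2, B1 meeting B2 and A2 disjoint from B1, extend both to
                # (A1 u A2)|B1 and A2|(B1 u B2)
                for a1, b1 in (s1, s1[::-1]):
                    for a2, b2 in (s2, s2[::-1]):
                        if a1 & a2 and b1 & b2 and not (a2 & b1):
                            new1 = (a1 | a2, b1)
                            new2 = (a2, b1 | b2)
                            if (_pair_key(new1) != _pair_key(s1)
                                    or _pair_key(new2) != _pair_key(s2)):
                                splits[i], splits[j] = new1, new2
                                changed = True
                                break
                    if changed:
                        break
                if changed:
                    break
        for a, b in splits:
            s = Split(a, b)
            absent = frozenset(all_taxa) - s.support_domain
            if absent:
                s = Split(s.side_a, s.side_b | absent)
            full.setdefault(s.key(), s)

    return SplitSystem(TaxonSet(sorted(all_taxa)), list(full.values()))


# ---------------------------------------------------------------------------
# support counting & filtering


def support_count(s: Split, inputs: list) -> int:
    """Number of inputs that support (do not contradict, and when visible,
    positively contain) the full split ``s``.

    An input whose taxa miss the split entirely, or see only a trivial
    restriction, supports vacuously.  A nontrivial restriction supports only
    if it equals one of the input's own splits; otherwise — in particular if
    it is incompatible with the input's split set — the input contributes 0.
    """
    count = 0
    for inp in inputs:
        sys = _as_split_system(inp)
        r = restrict_split(s, sys.taxa.labels)
        if r is None or r.is_trivial:
            count += 1
        elif any(r == t for t in sys.splits):
            count += 1
    return count


def filter_splits(system: SplitSystem, inputs: list,
                  params: FilterParams) -> SplitSystem:
    """Retain splits whose support count clears the threshold.

    Trivial splits are always retained (they carry no conflict).  Retained
    splits are annotated with their support count.
    """
    kept = []
    for s in system.splits:
        c = support_count(s, inputs)
        if s.is_trivial or params.keeps(c):
            kept.append(s.with_count(c))
    return SplitSystem(system.taxa, kept)


# ---------------------------------------------------------------------------
# splits graph (Buneman construction)


def build_splits_graph(system: SplitSystem, node_cap: int = 20000) -> SplitsGraph:
    """Canonical splits graph of a full split system.

    Nodes are the consistent side-choice vectors (one side per split, all
    pairwise intersecting); two nodes are adjacent iff they differ in exactly
    one split, and that split labels the edge.  Compatible systems give
    trees; k mutually incompatible splits give a 2^k hypercube face.  Each
    taxon attaches at the vector of sides containing it.
    """
    splits = list(system.splits)
    k = len(splits)
    if k == 0:
        g = nx.MultiGraph()
        g.add_node(0)
        return SplitsGraph(g, {t: 0 for t in system.taxa.labels}, splits)

    sides = [(s.side_a, s.side_b) for s in splits]
    vectors: list[tuple[int, ...]] = []

    def extend(prefix: list[int]) -> None:
        if len(vectors) > node_cap:
            raise SupernetError(
                "splits graph exceeds node cap; filter the system harder")
        i = len(prefix)
        if i == k:
            vectors.append(tuple(prefix))
            return
        for choice in (0, 1):
            side = sides[i][choice]
            if all(side & sides[j][prefix[j]] for j in range(i)):
                extend(prefix + [choice])

    extend([])
    index = {v: i for i, v in enumerate(vectors)}
    g = nx.MultiGraph()
    g.add_nodes_from(range(len(vectors)))
    for v, iv in index.items():
        for pos in range(k):
            w = v[:pos] + (1 - v[pos],) + v[pos + 1:]
            iw = index.get(w)
            if iw is not None and iv < iw:
                g.add_edge(iv, iw, split=pos)

    taxon_node = {}
    for t in system.taxa.labels:
        vec = tuple(0 if t in sides[i][0] else 1 for i in range(k))
        if vec not in index:
            raise SupernetError(f"taxon {t} has no node in the splits graph")
        taxon_node[t] = index[vec]
    return SplitsGraph(g, taxon_node, splits)


def split_sides_from_graph(sg: SplitsGraph, split_index: int):
    """Taxon bipartition induced by deleting one split's edge class."""
    h = nx.Graph()
    h.add_nodes_from(sg.graph.nodes)
    for u, v, data in sg.graph.edges(data=True):
        if data["split"] != split_index:
            h.add_edge(u, v)
    comps = list(nx.connected_components(h))
    out = []
    for comp in comps:
        taxa = frozenset(t for t, n in sg.taxon_node.items() if n in comp)
        if taxa:
            out.append(taxa)
    return out


# ---------------------------------------------------------------------------
# reticulation signature


def boxes_involving(system: SplitSystem, taxon: str) -> list[tuple[Split, Split]]:
    """Pairs of incompatible retained splits (boxes) around one taxon."""
    out = []
    for s, t in itertools.combinations(system.nontrivial(), 2):
        if not are_compatible(s, t):
            if taxon in s.support_domain and taxon in t.support_domain:
                out.append((s, t))
    return out
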