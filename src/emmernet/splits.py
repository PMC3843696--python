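"""Split algebra.

A *split* is an unordered bipartition ``A | B`` of a subset of the taxa (its
*support domain*); a split over a strict subset is *partial*.  Splits are the
common currency of this pipeline: alignment columns, binary insertion
markers, and tree edges all dissolve into splits, and split compatibility
(the four-point / four-gamete criterion) is what separates tree-like from
reticulate signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .io import MISSING_SYMBOLS, TaxonSet


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class Split:
    """An unordered bipartition of a taxon subset.

    Canonical form puts the side containing the lexicographically smallest
    taxon of the domain in ``side_a``.  ``support_count`` is filled by the
    supernetwork filter; ``informative`` is False for singleton-side splits
    (the analogue of an insertion detected in only one sample).
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    weight: float = 1.0
    support_count: int = 0

    def __post_init__(self) -> None:
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if not a or not b:
            raise SplitError("split sides must be nonempty")
        if a & b:
            raise SplitError("split sides must be disjoint")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def support_domain(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    @property
    def informative(self) -> bool:
        return not self.is_trivial

    def key(self) -> frozenset[frozenset[str]]:
        return frozenset((self.side_a, self.side_b))

    def __eq__(self, other) -> bool:
        return isinstance(other, Split) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"Split({{{a}}}|{{{b}}})"

    def with_count(self, count: int) -> "Split":
        return replace(self, support_count=count)


@dataclass
class SplitSystem:
    """A duplicate-free collection of splits over a full taxon set."""

    taxa: TaxonSet
    splits: list[Split] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict = {}
        for s in self.splits:
            extra = s.support_domain - set(self.taxa.labels)
            if extra:
                raise SplitError(f"split mentions unknown taxa: {sorted(extra)}")
            if s.key() not in seen:
                seen[s.key()] = s
        self.splits = list(seen.values())

    def __len__(self) -> int:
        return len(self.splits)

    def __contains__(self, s: Split) -> bool:
        return any(s == t for t in self.splits)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]


# ---------------------------------------------------------------------------
# constructors


def split_from_column(aln, column: int) -> list[Split]:
    """Dissolve one polymorphic alignment column into splits.

    Binary columns give one split; a k-state column gives one state-vs-rest
    split per state (duplicates canonicalised away).  Taxa with missing
    symbols are excluded, yielding a partial split.  Gap ``-`` counts as a
    fifth state (the indel signal), ambiguity codes count as missing.
    """
    col = aln.column(column)
    by_state: dict[str, set[str]] = {}
    for label, sym in zip(aln.taxa.labels, col):
        if sym in MISSING_SYMBOLS or sym == "?":
            continue
        by_state.setdefault(sym, set()).add(label)
    states = sorted(by_state)
    if len(states) < 2:
        raise SplitError(f"column {column} is monomorphic among non-missing taxa")
    domain = set().union(*by_state.values())
    out: list[Split] = []
    if len(states) == 2:
        out.append(Split(frozenset(by_state[states[0]]),
                         frozenset(by_state[states[1]])))
    else:
        for st in states:
            out.append(Split(frozenset(by_state[st]),
                             frozenset(domain - by_state[st])))
    # canonical dedup preserving order
    seen, uniq = set(), []
    for s in out:
        if s.key() not in seen:
            seen.add(s.key())
            uniq.append(s)
    return uniq


def split_from_marker(mm, marker: str) -> Split:
    """Present-vs-absent split of one binary marker; missing calls excluded.

    A marker present (or absent) in a single taxon yields a trivial split,
    flagged uninformative — such insertions are discarded from networks as
    phylogenetically uninformative.
    """
    col = mm.marker_column(marker)
    present = frozenset(l for l, v in zip(mm.taxa.labels, col) if v == 1)
    absent = frozenset(l for l, v in zip(mm.taxa.labels, col) if v == 0)
    if not present or not absent:
        raise SplitError(f"marker {marker!r} is constant among scored taxa")
    return Split(present, absent)


def splits_from_tree(tree) -> SplitSystem:
    """One split per internal edge, over the tree's own leaf set."""
    taxa = tree.taxa
    splits: list[Split] = []
    for cl in tree.clusters(include_trivial=True):
        rest = taxa - cl
        if cl and rest:
            splits.append(Split(frozenset(cl), frozenset(rest)))
    # trivial splits for leaves hanging off the root are not produced by
    # clusters(); add all leaf splits explicitly for completeness
    if len(taxa) > 1:
        for leaf in taxa:
            splits.append(Split(frozenset([leaf]), taxa - {leaf}))
    return SplitSystem(TaxonSet(sorted(taxa)), splits)


# ---------------------------------------------------------------------------
# predicates


def restrict_split(s: Split, taxa: Iterable[str]) -> Optional[Split]:
    """Intersect both sides with ``taxa``; None if a side empties."""
    taxa = set(taxa)
    a = s.side_a & taxa
    b = s.side_b & taxa
    if not a or not b:
        return None
    return Split(a, b, weight=s.weight)


def are_compatible(s: Split, t: Split) -> bool:
    """Four-point compatibility on the common support domain.

    Two splits can coexist on a single tree iff at least one of the four
    side intersections is empty.  Splits sharing fewer than four taxa are
    always compatible.
    """
    common = s.support_domain & t.support_domain
    if len(common) < 4:
        return True
    sa, sb = s.side_a & common, s.side_b & common
    ta, tb = t.side_a & common, t.side_b & common
    return not (sa & ta) or not (sa & tb) or not (sb & ta) or not (sb & tb)


def all_pairwise_compatible(splits: list[Split]) -> bool:
    return all(are_compatible(s, t) for s, t in itertools.combinations(splits, 2))
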