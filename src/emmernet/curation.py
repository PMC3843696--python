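"""Alignment editing and summary statistics applied before tree/network building.

The editing rules mirror the standard pre-processing of multi-locus
alignments for parsimony and split-network work: keep only polymorphic
positions, collapse multi-base indels to single positions so one insertion
event counts once, and drop sequences/columns riddled with unrecognised
bases.  Diversity (pi) and parsimony-informative counts summarise the curated
data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .io import AlignmentError, SeqAlignment

#: symbols that count as real states for editing rules (gap is a state here)
_RECOGNIZED = set("ACGT-")
#: symbols treated as missing for diversity/informativeness (gap included:
#: alignment artifacts must not inflate pi)
_MISSING_FOR_STATS = lambda sym: sym not in set("ACGT")


@dataclass
class DiversityResult:
    pi: float
    n_sequences: int
    n_sites: int
    n_alleles: int


def _states(column: str) -> set[str]:
    """Distinct non-missing states of a column (gap is missing here)."""
    return {c for c in column if c in set("ACGT")}


def extract_polymorphic_columns(aln: SeqAlignment) -> SeqAlignment:
    """Keep exactly the columns with >= 2 distinct non-missing states.

    Gap ``-`` counts as a fifth character state for this rule so that indel
    signal survives into split extraction.
    """
    keep = []
    for i in range(aln.n_columns):
        states = {c for c in aln.column(i) if c in _RECOGNIZED}
        if len(states) >= 2:
            keep.append(i)
    return aln.select_columns(keep)


def reduce_indels(aln: SeqAlignment) -> SeqAlignment:
    """Collapse each maximal run of columns with an identical gap pattern.

    A gap pattern is the set of gapped taxa; only runs of length > 1 whose
    pattern is nonempty and constant across the run are collapsed to their
    first column, so an indel of k > 1 bases counts as one position.
    """
    if aln.n_columns == 0:
        return aln
    patterns = [frozenset(l for l, c in zip(aln.taxa.labels, aln.column(i))
                          if c == "-")
                for i in range(aln.n_columns)]
    keep = []
    i = 0
    while i < aln.n_columns:
        j = i
        if patterns[i]:
            while j + 1 < aln.n_columns and patterns[j + 1] == patterns[i]:
                j += 1
        keep.append(i)
        i = j + 1
    return aln.select_columns(keep)


def drop_ambiguous(aln: SeqAlignment, max_unrecognized: int = 1) -> SeqAlignment:
    """Remove sequences, then columns, with multiple unrecognised bases.

    A base is unrecognised if outside ``{A,C,G,T,-}`` (i.e. N, ? or ambiguity
    codes).  Sequences are filtered first, then columns of the surviving
    sub-alignment; an entity is removed when it carries strictly more than
    ``max_unrecognized`` such bases.
    """
    if max_unrecognized < 1:
        raise ValueError("max_unrecognized must be >= 1")

    def n_bad(text: str) -> int:
        return sum(1 for c in text if c not in _RECOGNIZED)

    keep_taxa = [l for l, row in zip(aln.taxa.labels, aln.rows)
                 if n_bad(row) <= max_unrecognized]
    if not keep_taxa:
        raise AlignmentError("all sequences removed by ambiguity filter")
    sub = aln.select_taxa(keep_taxa)
    keep_cols = [i for i in range(sub.n_columns)
                 if n_bad(sub.column(i)) <= max_unrecognized]
    return sub.select_columns(keep_cols)


def nucleotide_diversity(aln: SeqAlignment) -> DiversityResult:
    """Per-site nucleotide diversity with the n/(n-1) correction.

    pi = (n/(n-1)) * mean over pairs of (differing sites / comparable sites),
    where a site is comparable for a pair when both sequences carry a plain
    A/C/G/T there (pairwise deletion of gaps and ambiguities).  Pairs with no
    comparable site are excluded with a warning.  ``n_alleles`` counts
    distinct full row strings.
    """
    n = aln.n_sequences
    if n < 2:
        raise AlignmentError("diversity needs at least 2 sequences")
    total = 0.0
    n_pairs = 0
    for r1, r2 in itertools.combinations(aln.rows, 2):
        comparable = 0
        diffs = 0
        for a, b in zip(r1, r2):
            if a in "ACGT" and b in "ACGT":
                comparable += 1
                if a != b:
                    diffs += 1
        if comparable == 0:
            warnings.warn("pair with no comparable sites excluded from pi")
            continue
        total += diffs / comparable
        n_pairs += 1
    if n_pairs == 0:
        raise AlignmentError("no comparable pairs for diversity")
    pi = (n / (n - 1)) * total / n_pairs
    return DiversityResult(pi=pi, n_sequences=n, n_sites=aln.n_columns,
                           n_alleles=len(set(aln.rows)))


def count_parsimony_informative(aln: SeqAlignment) -> int:
    """Columns with >= 2 states each carried by >= 2 sequences (gap/N missing)."""
    count = 0
    for i in range(aln.n_columns):
        col = aln.column(i)
        tallies: dict[str, int] = {}
        for c in col:
            if c in "ACGT":
                tallies[c] = tallies.get(c, 0) + 1
        if sum(1 for v in tallies.values() if v >= 2) >= 2:
            count += 1
    return count
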