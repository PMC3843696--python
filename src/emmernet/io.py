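"""Containers and file formats.

In-memory types (:class:`TaxonSet`, :class:`SeqAlignment`,
:class:`MarkerMatrix`) plus readers/writers for the standard formats the
pipeline touches: FASTA alignments (Biopython), Newick tree lists (dendropy),
delimited marker/metadata tables (pandas), and a NEXUS dialect with
TAXA + SPLITS blocks for split systems, compatible with common splits-graph
viewers.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

from .trees import Node, PhyloTree

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
#: symbols carrying no state information for nucleotide columns
MISSING_SYMBOLS = set("N?") | (IUPAC_DNA - set("ACGT"))


class InputError(ValueError):
    """Malformed input data."""


class AlignmentError(InputError):
    """Rows of unequal length or otherwise broken alignment."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class TaxonSet:
    """Ordered unique taxon labels with optional group metadata.

    ``groups`` maps a label to a ``{"category": ..., "region": ...}`` dict;
    categories in this study are wild / hulled / free-threshing / outgroup.
    """

    labels: list[str]
    groups: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise InputError("duplicate taxon labels")
        unknown = set(self.groups) - set(self.labels)
        if unknown:
            raise InputError(f"group metadata for unknown taxa: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)

    def category(self, label: str) -> str | None:
        return self.groups.get(label, {}).get("category")


@dataclass
class SeqAlignment:
    """Taxa x aligned nucleotide columns.

    Rows are upper-case strings over the IUPAC DNA alphabet plus ``-`` gap,
    ``?`` and ``N``.  ``column_origin`` records, for each current column, its
    index in the alignment this one was derived from (provenance through
    editing steps).
    """

    taxa: TaxonSet
    rows: list[str]
    locus_name: str = ""
    column_origin: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.taxa):
            raise AlignmentError("row count does not match taxon count")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        bad = set("".join(self.rows)) - IUPAC_DNA - {"-", "?"}
        if bad:
            raise AlignmentError(f"non-IUPAC symbols: {sorted(bad)}")
        if self.column_origin is None:
            self.column_origin = list(range(self.n_columns))

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def row(self, label: str) -> str:
        return self.rows[self.taxa.labels.index(label)]

    def select_columns(self, idx: list[int]) -> "SeqAlignment":
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        origin = [self.column_origin[i] for i in idx]
        return SeqAlignment(self.taxa, rows, self.locus_name, origin)

    def select_taxa(self, labels: list[str]) -> "SeqAlignment":
        keep = [l for l in self.taxa.labels if l in set(labels)]
        rows = [self.row(l) for l in keep]
        groups = {l: g for l, g in self.taxa.groups.items() if l in set(keep)}
        return SeqAlignment(TaxonSet(keep, groups), rows, self.locus_name,
                            list(self.column_origin))


@dataclass
class MarkerMatrix:
    """Taxa x named binary insertion markers (1 present, 0 absent, None missing)."""

    taxa: TaxonSet
    marker_names: list[str]
    calls: list[list[int | None]]  # row per taxon

    def __post_init__(self) -> None:
        if len(self.marker_names) != len(set(self.marker_names)):
            raise InputError("duplicate marker names")
        if len(self.calls) != len(self.taxa):
            raise InputError("call row count does not match taxon count")
        for row in self.calls:
            if len(row) != len(self.marker_names):
                raise InputError("call row length does not match marker count")
            if any(v not in (0, 1, None) for v in row):
                raise InputError("marker calls must be 0, 1 or missing")

    def marker_column(self, name: str) -> list[int | None]:
        j = self.marker_names.index(name)
        return [row[j] for row in self.calls]


# ---------------------------------------------------------------------------
# FASTA


def read_alignment(source: str, locus_name: str = "",
                   taxa_groups: dict[str, dict[str, str]] | None = None) -> SeqAlignment:
    """Parse FASTA text into an alignment (taxa in file order, upper-cased)."""
    handle = _io.StringIO(source)
    labels: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(handle, "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not labels:
        raise InputError("no FASTA records found")
    if len(labels) != len(set(labels)):
        raise InputError("duplicate record labels in FASTA")
    taxa = TaxonSet(labels, taxa_groups or {})
    return SeqAlignment(taxa, rows, locus_name)


def write_alignment(aln: SeqAlignment) -> str:
    out = []
    for label, row in zip(aln.taxa.labels, aln.rows):
        out.append(f">{label}\n{row}\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# marker tables


def read_marker_matrix(source: str, missing_token: str = "NA",
                       sep: str = "\t") -> MarkerMatrix:
    """Parse a delimited table: header of marker names, first column = taxon."""
    df = pd.read_csv(_io.StringIO(source), sep=sep, dtype=str, index_col=0)
    if df.empty and df.shape[1] == 0:
        raise InputError("empty marker table")
    calls: list[list[int | None]] = []
    for label, row in df.iterrows():
        parsed: list[int | None] = []
        for name, cell in row.items():
            cell = str(cell).strip()
            if cell == missing_token or cell.lower() == "nan":
                parsed.append(None)
            elif cell in ("0", "1"):
                parsed.append(int(cell))
            else:
                raise InputError(
                    f"non-binary marker call {cell!r} for taxon {label!r}, marker {name!r}")
        calls.append(parsed)
    taxa = TaxonSet([str(l) for l in df.index])
    return MarkerMatrix(taxa, [str(c) for c in df.columns], calls)


def write_marker_matrix(mm: MarkerMatrix, missing_token: str = "NA",
                        sep: str = "\t") -> str:
    df = pd.DataFrame(
        [[missing_token if v is None else v for v in row] for row in mm.calls],
        index=mm.taxa.labels, columns=mm.marker_names)
    return df.to_csv(sep=sep, index_label="taxon")


def read_group_table(source: str, sep: str = "\t") -> dict[str, dict[str, str]]:
    """Sidecar metadata: columns label, category, region."""
    df = pd.read_csv(_io.StringIO(source), sep=sep, dtype=str)
    groups = {}
    for _, row in df.iterrows():
        groups[row["label"]] = {"category": row.get("category", ""),
                                "region": row.get("region", "")}
    return groups


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def _from_dendropy(node: dendropy.Node) -> Node:
    n = Node()
    if node.taxon is not None:
        n.label = node.taxon.label
    elif node.label:
        # numeric internal labels are supports
        try:
            n.support = float(node.label)
        except ValueError:
            pass
    n.length = node.edge.length
    n.children = [_from_dendropy(c) for c in node.child_nodes()]
    return n


def read_trees(source: str, rooted: bool = False) -> list[PhyloTree]:
    """Parse Newick text (one tree per line / semicolon-separated)."""
    try:
        tree_list = dendropy.TreeList.get(
            data=source, schema="newick",
            rooting="force-rooted" if rooted else "force-unrooted",
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise InputError(f"Newick parse error: {exc}") from exc
    out = []
    for t in tree_list:
        root = _from_dendropy(t.seed_node)
        if not rooted and len(root.children) == 2:
            # collapse the basal bifurcation: unrooted trees have no
            # meaningful degree-2 root
            a, b = root.children
            if b.is_leaf and not a.is_leaf:
                a, b = b, a
            if not b.is_leaf:
                root = Node(children=[a] + b.children)
        out.append(PhyloTree(root, rooted))
    return out


def write_trees(trees: list[PhyloTree]) -> str:
    def newick(node: Node) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(newick(c) for c in node.children)
            sup = "" if node.support is None else format(node.support, "g")
            body = f"({inner}){sup}"
        if node.length is not None:
            body += f":{node.length:g}"
        return body

    return "".join(newick(t.root) + ";\n" for t in trees)


# ---------------------------------------------------------------------------
# splits NEXUS


def write_splits_nexus(system) -> str:
    """Emit TAXA + SPLITS blocks; sides as 1-based index lists of side_a."""
    labels = list(system.taxa.labels)
    index = {lab: i + 1 for i, lab in enumerate(labels)}
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={len(labels)};",
             "  TAXLABELS"]
    lines += [f"    {lab}" for lab in labels]
    lines += ["  ;", "END;", "", "BEGIN SPLITS;",
              f"  DIMENSIONS NTAX={len(labels)} NSPLITS={len(system.splits)};",
              "  FORMAT WEIGHTS=YES;", "  MATRIX"]
    for k, s in enumerate(sorted(system.splits, key=lambda s: sorted(s.side_a)), 1):
        side = " ".join(str(index[t]) for t in sorted(s.side_a, key=labels.index))
        lines.append(f"    [{k}] {s.weight:g} {side},")
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)


def read_splits_nexus(source: str):
    """Read the dialect written by :func:`write_splits_nexus`."""
    from .splits import Split, SplitSystem

    taxa_m = re.search(r"TAXLABELS(.*?);", source, re.S | re.I)
    if not taxa_m:
        raise InputError("no TAXLABELS in NEXUS input")
    labels = taxa_m.group(1).split()
    matrix_m = re.search(r"BEGIN SPLITS;.*?MATRIX(.*?);", source, re.S | re.I)
    if not matrix_m:
        raise InputError("no SPLITS matrix in NEXUS input")
    splits = []
    for line in matrix_m.group(1).strip().splitlines():
        line = re.sub(r"\[.*?\]", "", line).strip().rstrip(",").strip()
        if not line:
            continue
        parts = line.split()
        weight = float(parts[0])
        side_a = frozenset(labels[int(i) - 1] for i in parts[1:])
        side_b = frozenset(labels) - side_a
        splits.append(Split(side_a, side_b, weight=weight))
    return SplitSystem(TaxonSet(labels), splits)
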