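#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the three data layers of the study design: (1) an amplicon-style
haplotype alignment evolved without homoplasy on a known genealogy, with a
planted mosaic (hybrid) haplotype; (2) a binary retroelement-insertion
marker matrix for three populations plus a mosaic hybrid individual; (3) a
set of per-locus gene trees carrying one planted reticulation each, with
leaf dropout emulating uneven locus coverage.  Everything is seeded; the
planted truth is written alongside the data.
"""

import json
import pathlib
import random

from emmernet.io import write_alignment, write_marker_matrix, write_trees
from emmernet.synthdata import (gen_alignment_on_tree, gen_discordant_trees,
                                gen_hybrid_markers)
from emmernet.trees import random_binary_tree

SEED = 20260925
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = random.Random(SEED)

    # amplicon alignment on a 12-taxon genealogy
    genealogy = random_binary_tree([f"acc{i:02d}" for i in range(12)], rng)
    aln, _ = gen_alignment_on_tree(genealogy, L=60, subst_rate=0.6, seed=SEED)
    (OUT / "amplicon.fasta").write_text(write_alignment(aln))
    (OUT / "amplicon_genealogy.nwk").write_text(write_trees([genealogy]))

    # marker matrix: 3 populations x 5 accessions, 12 markers, 1 hybrid
    mm, truth = gen_hybrid_markers([5, 5, 5], 12,
                                   hybrid_spec=[(0, 1, 0.5)], seed=SEED)
    (OUT / "markers.tsv").write_text(write_marker_matrix(mm))
    (OUT / "markers_truth.json").write_text(json.dumps(
        {"hybrids": truth.hybrids, "populations": truth.populations},
        indent=2))

    # 15 partial gene trees with one planted reticulation each
    species = random_binary_tree([f"acc{i:02d}" for i in range(8)], rng)
    trees, tree_truth = gen_discordant_trees(species, n_loci=15,
                                             hybrid_edges=1,
                                             taxon_dropout=0.15, seed=SEED)
    (OUT / "species_tree.nwk").write_text(write_trees([species]))
    (OUT / "locus_trees.nwk").write_text(write_trees(trees))
    (OUT / "locus_truth.json").write_text(json.dumps(
        {"hybridizations_per_locus": tree_truth.hybridizations_per_locus,
         "n_loci": len(trees)}, indent=2))

    print(f"wrote amplicon alignment ({aln.n_sequences} x {aln.n_columns}), "
          f"marker matrix ({len(mm.taxa)} x {len(mm.marker_names)}), "
          f"{len(trees)} locus trees -> {OUT}")


if __name__ == "__main__":
    main()
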