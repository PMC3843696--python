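# emmernet

Reticulation detection for predominantly self-pollinating plant lineages.

Domesticated emmer wheat — like many selfing crops — carries different,
mutually conflicting genealogies in different parts of its genome. A single
bifurcating tree cannot represent such an ancestry; networks can. This
package implements, as a tested and reusable pipeline, the analysis chain
used to make that case:

* **Split algebra** — alignment columns, binary retroelement-insertion
  markers and tree edges all dissolve into (partial) splits A|B; two splits
  can coexist on one tree iff one of their four side intersections is empty
  (the four-gamete test).
* **Median-joining haplotype networks** — minimum spanning networks over
  Hamming distance plus inferred median (Steiner) haplotypes, for allele
  data where ancestors persist alongside descendants.
* **Filtered supernetworks** — partial splits extended to the full taxon
  set by Z-closure, filtered by a `minSupportingTrees`-style support count,
  and rendered as a Buneman splits graph in which incompatible splits form
  boxes: the visual signature of reticulation.
* **Parsimony incongruence** — exact and heuristic maximum-parsimony
  search, consensus and bootstrap, and the concatenated-versus-per-locus
  score ratio `L(concat) / Σ L(locus_i)` (1 under a shared history, > 1
  under gene-tree conflict).
* **Hybridization numbers** — for conflicting rooted tree pairs, the exact
  minimum number of reticulations, via maximum acyclic agreement forests
  (`h = |MAAF| − 1`).
* **Mixing simulation** — a forward-time model of mixed stands of a selfing
  annual: N lines, L diagnostic loci, per-generation outcross frequency c,
  free-recombination mosaics, no selection; tracks the frequency of intact
  founder genotypes.
* **Synthetic data** — seeded generators planting known hybrids,
  reticulations and splits, so every stage is scored against ground truth.

## Worked example

Synthetic markers for three populations with one mosaic hybrid, run through
the supernetwork track:

```python
import emmernet as em
from emmernet.supernet import FilterParams, boxes_involving

mm, truth = em.gen_hybrid_markers([5, 5, 5], 12,
                                  hybrid_spec=[(0, 1, 0.5)], seed=0)
inputs = [em.SplitSystem(mm.taxa, [s])
          for s in (em.split_from_marker(mm, m) for m in mm.marker_names)
          if s.informative]
full = em.zclosure(inputs, runs=5, seed=0)
kept = em.filter_splits(full, inputs, FilterParams(0, strict_greater=True))
print(len(inputs), len(kept), len(boxes_involving(kept, "hyb1")))
```

prints `12 5 1`: twelve informative marker splits collapse to five retained
full splits, and the hybrid sits inside one box — a pair of incompatible
splits tying it to each parental population, i.e. a reticulate placement.

The mixing model, at its reference conditions:

```python
cfg = em.SimConfig(k=2, c=0.01, N=1000, L=20, generations=200,
                   replicates=20, seed=1)
traj = em.simulate(cfg)
print(round(100 * traj.mean_freq[-1], 2), traj.first_below(0.10))
```

prints `4.27 153`: with two equal founder populations and 1% outcrossing,
only ~4% of lines still carry an intact founder genotype after 200
generations, crossing below 10% around generation 153 — rare outcrossing is
enough to turn a mixed stand into a genetic mosaic.

The same analyses are scripted as narrative drivers under `analysis/`
(`01_generate_data.py` … `06_mixing_simulation.py`), writing their tables
to `results/`, and as a CLI:

```
emmernet mosaic --outcross-rate 0.01 --generations 200 --outdir out/
emmernet supernet --markers markers.tsv --min-supporting 3 --outdir out/
emmernet run figD --seed 1 --outdir out/
```

## Layout

```
src/emmernet/     library: io, curation, splits, haplonet, parsimony,
                  supernet, hybrid, mosaic, synthdata, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite incl. brute-force oracles and acceptance tests
scripts/          acceptance.py
docs/methods.md   model assumptions, defaults, numerical choices, limits
```
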