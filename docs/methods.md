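# Methods

`emmernet` implements the analysis chain used to ask whether a predominantly
self-pollinating crop lineage (the motivating case is domesticated emmer
wheat, *Triticum turgidum*) has a tree-like or a reticulate ancestry. The
chain has three independent evidence tracks — haplotype networks from
amplicon alleles, filtered supernetworks from binary retroelement-insertion
markers and from per-locus gene trees, and parsimony incongruence plus
pairwise hybridization counts — and one forward-time simulation showing that
rare outcrossing in mixed stands is sufficient to generate the observed
mosaic genotypes. Wet-lab genotyping is replaced by seeded synthetic-data
generators that plant known structure, so every stage is testable against
ground truth.

## Split algebra

A *split* A|B is an unordered bipartition of a subset of the taxa (its
support domain); splits over strict subsets are *partial*. Alignment
columns, binary markers and tree edges all dissolve into splits:

* a binary column gives one split (taxa with state 1 vs state 2); a k-state
  column gives one state-vs-rest split per state. Taxa with missing symbols
  are excluded, yielding partial splits rather than imputed calls. The gap
  symbol is a fifth character state here (indel signal is real signal),
  while ambiguity codes are missing.
* a binary presence/absence marker gives its present-vs-absent split;
  markers present (or absent) in a single individual are flagged
  uninformative and dropped from network building.
* a tree contributes one split per edge, over its own leaf set.

Two splits are compatible iff, on their common domain, at least one of the
four side intersections is empty (the four-point condition; for binary
characters this is the four-gamete test, and the test suite verifies the
equivalence against a direct gamete counter). Splits sharing fewer than
four taxa are vacuously compatible. Canonical form places the side with the
lexicographically smallest taxon first, making split sets order-free.

## Curation rules

Alignment editing follows the conventions of parsimony/network work on
amplicon data: keep only polymorphic columns (two or more distinct states,
gap counted as a state); collapse each maximal run of columns with an
identical nonempty gap pattern to a single column, so a k-base indel counts
as one event; remove sequences, then columns, carrying more than
`max_unrecognized` (default 1) symbols outside `{A,C,G,T,-}`. The
sequences-before-columns order is fixed and documented because the two
orders give different results on pathological inputs.

Nucleotide diversity is computed as
`pi = (n/(n-1)) x mean over pairs of (differing sites / comparable sites)`
with pairwise deletion (a site is comparable for a pair when both carry a
plain base; gaps never count toward pi, so alignment artifacts cannot
inflate it). `n_alleles` counts distinct full sequences. A
parsimony-informative column has at least two states each carried by at
least two sequences.

## Median-joining networks

Identical (curated) sequences collapse to haplotypes weighted by accession
count and annotated with group composition. The network construction
follows the median-joining scheme: the epsilon-relaxed minimum spanning
network (an edge belongs iff its Hamming length is within epsilon of the
bottleneck/minimax path length between its ends; epsilon = 0 gives the
union of all minimum spanning trees) is augmented by *median vectors* —
per-position majorities of triples with at least two network edges among
their pairs. A median is added only when it strictly reduces the total
spanning cost; the largest reduction wins, ties break on the
lexicographically smallest state vector, and unobserved vectors whose
network degree falls to two or less are pruned. Observed haplotypes are
never removed, and an iteration cap guards termination. Defaults:
epsilon 0, uniform character weights.

On small instances (up to 5 haplotypes and 6 binary sites) the resulting
network cost equals the exact hypercube Steiner minimum computed by a
Dreyfus–Wagner dynamic programme; this equivalence is asserted in the test
suite over seeded random fixtures. No maximum-parsimony post-filtering of
the network is applied.

## Maximum parsimony

Scoring uses the unit-cost Sankoff recursion, exact on multifurcating
trees and identical to Fitch on binary ones; gaps and ambiguities are
wildcards by default (a `gap_as_state` mode treats the gap as a fifth
state — published character counts can be sensitive to this choice, so both
are exposed). Search is exact (all unrooted topologies by sequential edge
insertion) up to `exhaustive_limit` taxa, default 9 (135,135 topologies,
feasible with column-pattern compression); above that, each of
`n_jumbles` (default 10) random-addition-order stepwise insertions is
refined by nearest-neighbour-interchange hill climbing. All co-optimal
topologies found are kept, canonicalised, and sorted for reproducibility.
NNI rather than SPR refinement is a deliberate simplicity/verifiability
trade-off: at the matrix sizes involved the heuristic reaches the
exhaustive optimum on at least 95% of random fixtures (asserted in the
suite).

Strict and majority-rule consensus operate on unrooted split sets; the
bootstrap resamples columns with replacement, takes one canonical best tree
per replicate, and reports cluster percentages. The incongruence
diagnostic is the ratio of the concatenated-matrix MP score to the sum of
per-locus MP scores: exactly 1 when one tree fits all loci,
superadditively above 1 under gene-tree conflict.

## Filtered supernetworks

Partial splits are extended to the full taxon set with the Z-closure rule:
for orientations A1|B1, A2|B2 with A1 meeting A2, B1 meeting B2 and A2
disjoint from B1, both splits extend to (A1 u A2)|B1 and A2|(B1 u B2). The
rule is swept in randomised order to a fixed point (sides only grow, so
termination is guaranteed); splits still partial afterwards are completed
by placing absent taxa on the canonical second side (a flagless discard
alternative was considered and rejected — completion preserves signal and
is reported as such). The union over several randomised runs (default 5)
compensates for the closure's order dependence. On conflict-free partial
trees the closure loses no signal: restricted to any input's taxa it
contains that input's nontrivial splits (asserted in the suite).

A full split's support count is the number of inputs that do not
contradict it and positively contain it where visible: an input whose taxa
miss the split (or see only a trivial restriction) supports vacuously; a
nontrivial restriction must equal one of the input's own splits. The
`minSupportingTrees`-style filter retains splits whose count exceeds the
threshold (strictly by default, matching the "congruent with more than m
others" reading); trivial splits always survive. Filtering is antitone in
the threshold. Raw splits used as inputs are treated as one-split inputs,
unifying the markers-as-splits and trees-as-inputs runs; vacuous support is
counted (the cited parameter's behaviour on absent taxa is not documented,
so the choice is fixed here and exposed).

The splits graph is the Buneman construction: nodes are consistent
side-choice vectors, edges connect vectors differing in one split and are
labelled by it. Compatible systems yield trees (edge count = split count);
k mutually incompatible splits yield a 2^k hypercube face — the "boxes"
whose presence around a taxon is the reticulation signature. Deleting one
split's edge class bipartitions the taxa exactly by that split. A node cap
aborts construction of under-filtered systems.

## Hybridization numbers

Rooted tree pairs are restricted to common leaves; a pair conflicts iff
some cluster of one overlaps but neither contains nor is contained in a
cluster of the other. The minimum hybridization number equals one less
than the size of a maximum acyclic agreement forest. It is computed
exactly by iterative deepening over edge subsets cut in the first tree
(with the standard artificial root-leaf added): each cut set induces a leaf
partition, validated by vertex-disjoint embeddings and identical restricted
cluster families in both trees, plus acyclicity of the component-ancestry
digraph. An independent exhaustive oracle enumerates all leaf-set
partitions; the two agree on every instance up to 7 common taxa (asserted
in the suite). Exactness is restricted to `exact_limit` (default 12)
common taxa; soft polytomies are resolved exhaustively up to degree 5
(beyond that they are treated as hard, with a warning). The pairwise
report examines all C(k,2) pairs and averages hybridization numbers over
conflicting pairs only.

This exact small-instance search deliberately replaces the heuristic
"autumn algorithm" used for the same quantity at larger scales: on
instances where both are exact they compute the same number, and the exact
search is verifiable against the enumeration oracle.

## Mixing simulation

Lines in a cultivated stand are modelled as haploid multilocus genotypes
(full selfing keeps lines homozygous, so the heterozygous-then-segregating
generations after an outcross are absorbed into a single free-recombination
mosaic). Founder populations are fixed for population-diagnostic alleles
at all `L` loci. Each generation every line is succeeded by selfed seed
except for outcross events at frequency `c`:

* `maternal-only`: each line initiates an outcross with probability `c`;
  only the initiator's successor is a mosaic. With all-distinct genotypes
  the founder-genotype frequency follows `(1-c)^t` exactly — the analytic
  envelope asserted in the suite.
* `symmetric-pair` (default): each line initiates with probability `c` and
  is paired with a uniformly chosen partner; both successors are
  independent mosaics. About `2c` of lines are affected per generation.

The default is symmetric-pair because the maternal-only envelope at the
reference parameters (`c = 0.01`, 200 generations) cannot fall below
`0.99^200 ≈ 0.134`, whereas the reference claim is erosion below 10% —
i.e. the claim implies events that affect both participating lineages.
Under symmetric-pair with two equal founder populations, N = 1000 lines,
L = 20 loci and 20 replicates, the mean founder-genotype frequency at
generation 200 is ≈ 4% (computed by `scripts/acceptance.py` and the test
suite at run time). There is no selection and no mutation, so per-locus
allele frequencies are conserved in expectation (asserted within
Monte-Carlo error). Defaults N = 1000, L = 20, 20 replicates; the tracked
frequency is insensitive to N and L well above the regime where recombinant
genotypes can coincide with founders by chance (probability ~2^-L per
event).

## Synthetic data

* **Alignments on a tree** use infinite-sites-style generation: a site
  mutates at most once, on an edge chosen proportionally to length. Clean
  data therefore satisfy exact invariants (every polymorphic column is a
  tree split; columns are mutually compatible; MP recovers the generating
  topology) instead of statistical ones. A `subst_rate` below 1 leaves a
  corresponding fraction of sites constant. This deliberately omits
  homoplasy, rate variation and realistic base composition: passing tests
  certify algorithmic correctness on signal-bearing data, not robustness
  to homoplasy.
* **Marker matrices** deal markers round-robin to populations as
  diagnostic blocks; hybrids receive a per-marker mixture of two parents
  with at least one diagnostic marker of each forced, guaranteeing the
  defining pattern: each marker occurs in some parent population, the
  combination only in the hybrid.
* **Discordant gene trees** apply a fixed number of random rooted SPR
  moves (one planted reticulation each) to a species tree, then drop
  leaves independently to emulate partial locus coverage.

All generators are deterministic under a seed and return a truth object
sufficient to score recovery without re-inspecting internals.

## Problem sizes and numerical choices

The analysis drivers and test suite run at desk scale by design: exhaustive
MP oracles at 7–8 taxa, agreement-forest oracles at ≤7 taxa, Steiner
oracles at ≤5 haplotypes × ≤6 sites, supernetworks over ≤16 taxa, and the
simulation at its reference N = 1000. Published full-data quantities
(hundreds of accessions, 21 loci) are inputs the pipeline accepts but are
not recomputed here. Ties are broken deterministically everywhere
(lexicographic state vectors, sorted canonical Newick, seeded RNG streams);
all randomness flows from explicit seeds, and manifest-driven re-runs are
byte-reproducible.

## Known limitations

* The MP heuristic is NNI-based; on adversarial matrices it can stop in a
  local optimum (observed on ~2–5% of random fixtures, always at a score
  no better than the optimum).
* Median-joining is greedy; its Steiner-optimality is asserted only at the
  oracle-checked scale.
* Z-closure output depends on sweep order; multiple randomised runs reduce
  but do not formally eliminate order effects.
* The agreement-forest search is exponential and refuses instances above
  its exact limit rather than degrade silently.
* The simulation ignores diploidy, linkage, selection, seed banks and
  overlapping generations; it models exactly the genotype-mosaic bookkeeping
  needed for the founder-frequency claim.
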