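# Methods

## Model

`abmotif` searches for functional modules — sets of proteins, represented by
their COG orthology classes, that all participate in the same cellular
subsystem — whose presence discriminates phenotype-expressing from
non-expressing organisms. Two assumptions underpin the method:

* within one organism, a functional module forms a **maximal clique** of the
  organism's functional-association network (every member pair is
  associated, and the set cannot be extended);
* a module related to the phenotype is **conserved** in many positive and
  few negative organisms.

Rather than enumerating cliques per organism and comparing them across
networks (a multi-way comparison over exponentially large sets), the
per-organism networks are fused into a single *two-typed, divided network*:

* vertices are (organism, COG) pairs, partitioned into per-organism
  divisions labelled positive or negative;
* *intra-organismal* edges are the input associations with combined score at
  or above the edge threshold;
* *orthology* edges join (A, c) to (B, c) whenever both organisms contain
  COG c — co-presence only, no score condition, because COG identity is
  itself the orthology statement;
* *conserved-association* edges join (A, c1) to (B, c2), c1 ≠ c2, iff the
  thresholded association c1–c2 exists in **both** A and B.

A module conserved across a set of organisms then appears as a single
maximal clique of the fused graph, and the whole comparison collapses to one
clique enumeration.

### Non-product maximal cliques

Conserved modules produce *product* cliques — (organism set) × (COG set),
one orthologous sub-clique per organism. The edge rules, however, also admit
maximal cliques without this structure: three organisms over COGs {x, y, z}
with association edges {xy, xz}, {xy, yz} and {xz, yz} respectively make
{(A, x), (B, y), (C, z)} a maximal clique chained purely through
conserved-association edges, with no orthology inside it. These are
legitimate maximal cliques of the model but not conserved modules in the
one-to-one orthology sense. The package therefore keeps every module's exact
vertex set, exposes an `is_product` flag, and reports the COG set as the
union over vertices. In random and planted test cohorts such cliques are
rare; the regression suite pins the smallest known example.

## Enumeration

The enumerator is the pivotless Bron–Kerbosch recursion over CLIQUE / CAND /
NOT vertex sets, with candidate iteration in lexicographic (organism, COG)
order so that the search tree, node counts and output order are fully
deterministic. At a leaf (CAND empty) a clique is reported iff NOT is empty
(maximality) and the type counts satisfy c(S, p) ≥ α and c(S, n) ≤ β. The
empty vertex set is never reported. Two bounds prune the tree, in three
selectable modes (`none`, `beta_only`, `alpha_beta`):

* **β bound** — applied to CLIQUE ∪ {current} *before* recursion: type
  counts are monotone under superset, so once the negative count exceeds β
  no descendant can recover. Testing the extended clique rather than CLIQUE
  alone is sound and at least as tight.
* **α bound** — c(NEWCLIQUE ∪ NEWCAND, p) upper-bounds the positive count
  of every descendant; recursion is skipped when it falls below α. The
  computation exits early once α reachable positives are confirmed.

In every mode, a processed candidate moves from CAND to NOT even when its
subtree was pruned; the NOT-empty leaf test then still certifies maximality
globally, which is why pruning never changes the output set. Pivoting and
degeneracy ordering are deliberately not used: the two bounds are the
algorithm's own search-space reduction, and node-count comparisons between
the three modes are part of the package's contract. Adjacency is built once
as bitsets (Python integers) and shared read-only by the recursion.

Worst-case behaviour is the Moon–Moser bound: a complete multipartite graph
with k parts of 3 has 3^k maximal cliques, so enumeration is exponential in
general; the (α, β)-criterion's value is precisely that the bounds cut the
tree long before that limit on phenotype-filtered instances. A conserved
module planted in m COGs × k organisms still forms a complete (m·k)-vertex
subgraph that costs the pivotless recursion O(2^(m·k)) nodes to traverse,
which is what limits desk-scale cohort sizes in the test suite.

## Statistics

Both the (α, β) pair screening and per-module scoring use the inclusive
one-sided hypergeometric upper tail P(X ≥ observed): population = cohort,
successes = positive organisms, sample = α + β (or the module's organism
count), observed = α (or the module's positive count). The tail is an
enrichment test toward positives, the only reading that reproduces the
selected pairs (7, 0), (8, 1), (9, 2) for the 9/8 layout at p ≤ 0.005. The
tail is computed by exact rational summation (`fractions.Fraction` over
`math.comb`) and rounded to float once, so it is exact to float precision at
any cohort size the package targets; the test suite cross-checks against
`scipy.stats.hypergeom`. Selection scans α from 1 (α = 0 is reserved for
the explicit all-cliques mode), keeps α ≥ β, includes ties at the threshold,
retains per β only the smallest α, and applies no multiple-testing
correction.

## Phylogenetic diversity score

S_p = (PP − PN − NN) / (PP + PN + NN), with PP and NN the sums of pairwise
distances over *ordered* pairs within the module's positive and negative
carriers and PN the sum over positive × negative pairs. The ordered-pair
convention double-counts within-type pairs relative to cross-type pairs;
this asymmetry is part of the score's definition and is implemented as
written rather than "corrected". S_p ∈ [−1, 1], is invariant to rescaling
all distances, and never decreases when positive carriers grow further
apart. When the denominator is zero (module in ≤ 1 organism, or a
degenerate all-zero matrix) the score is undefined; a sentinel 0.0 is
returned with a logged warning and rendered as `NA` in the output table.
Distance matrices are validated for symmetry to 1e-9 relative tolerance and
symmetrized by averaging within it; larger asymmetry is a hard error.

## Synthetic cohorts

The generator emulates the pipeline's inputs at desk scale: a shared COG
universe, per-organism presence draws, sparse random background
associations with STRING-like integer scores, planted conserved cliques
with known carriers, and a random symmetric organism distance matrix.
Defaults, chosen once as a realistic small comparative cohort:

| parameter | default | rationale |
|---|---|---|
| n_pos / n_neg | 9 / 8 | the classic hydrogen-production cohort layout |
| universe_size | 30 | desk-scale stand-in for the ~4.5k COG catalogue |
| presence_prob | 0.5 | a COG universe shared by roughly half the cohort |
| background_edge_prob | 0.05 | sparse spurious associations |
| background_score_range | 1–999 | uniform over the STRING combined-score scale |
| planted edge_score | 900 | comfortably above the high-confidence threshold |
| edge threshold (pipeline) | 700 | STRING's conventional high-confidence cut |

Random streams are split per organism with `numpy.random.SeedSequence`
spawning, so enlarging a cohort never perturbs existing organisms' draws.
The generator does **not** emulate STRING's evidence channels, realistic
(scale-free) degree distributions, correlated COG presence along lineages,
or missing-data patterns; passing tests therefore demonstrate correctness
of the algorithmics and pipeline plumbing on the stated noise model, not
performance on real STRING exports. With background noise a planted clique
may be absorbed into a larger maximal clique, so recovery is asserted as
containment of the planted COG set, not set equality.

## Pipeline choices

* **Protein → COG projection.** When a mapping table is supplied, protein
  pairs collapsing onto one COG pair keep the **maximum** combined score
  (the most confident evidence for the association), pairs mapping to a
  single COG are dropped as self-loops, and unmapped proteins are dropped
  and counted in a report. Reversed duplicate edges likewise merge by
  maximum. Thresholding happens after projection. COGs left without any
  surviving association are kept as isolated vertices — they can still
  anchor orthology-only modules, and a `min_cogs` reporting filter
  (default 1) lets users hide single-COG output downstream.
* **Union over pairs.** Running several selected (α, β) pairs is
  implemented as one enumeration at (min α, max β) followed by an any-pair
  filter on type counts; this provably equals the deduplicated union of
  per-pair runs and is cheaper.
* **Edge-threshold selection.** The ladder defaults to 999, 950, …, 500
  (descending, 50-point steps; configurable, 999 always included).
  *Accuracy* is defined as validation-set recall: the fraction of known
  phenotype-related COGs appearing in at least one output module. The first
  ladder value reaching the accuracy target (default 0.75) is selected;
  otherwise the best-accuracy value is returned with a warning. The
  unique-COG count per threshold and its successive differences are
  reported as a secondary diagnostic only — interpreting the largest jump
  is left to the analyst.
* **Subsampling robustness.** Organisms are grouped (e.g. by genus); each
  trial keeps one organism per group, draws a subset size from a
  configurable range, reruns the pipeline and ranks modules by
  (p-value ascending, S_p descending). Reported stability is the pairwise
  overlap fraction of top-k COG-set lists (k = 10 by default), with
  |A ∩ B| / min(|A|, |B|); two empty lists count as fully overlapping.
  Trials that would contain no positive organism are redrawn
  (deterministically, bounded retries).
* **Determinism.** Identical inputs, config and seed give byte-identical
  outputs: set-valued fields are emitted sorted, floats are written with
  `repr`, the manifest contains no timestamps, and module order is the
  canonical (|COG set| descending, lexicographic) order.
* **Module table.** The TSV flattens modules to COG / organism sets; the
  JSON sidecar additionally stores exact vertex lists, which the TSV cannot
  represent for non-product cliques — round-tripping through JSON is
  lossless for every module, through TSV for product modules.
* **Out-of-range α.** Requesting α above the number of positive organisms
  (or β above the negatives) is satisfiable by nothing and returns an empty
  result rather than an error; only negative parameters are rejected.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on generated cohorts sized
for an ordinary workstation: 200 random cohorts of ≤ 6 organisms × ≤ 8 COGs
for the exhaustive-oracle comparison (every feasible (α, β), all three
bound modes), hydrogen-layout cohorts (9/8 organisms, 30 COGs) for
planted-module recovery — 10 noise-free seeds at two (α, β) probes and 50
noisy seeds at (7, 0) — and small multipartite worst-case instances. These
sizes are the package's own choice of desk-scale study conditions.

## Known limitations

* The quasi-clique post-processing step that tolerates missing edges in
  real data (the DENSE algorithm) is out of scope; cliques are exact here.
* The hypergeometric screen ignores phylogenetic correlation between
  organisms; S_p quantifies it post hoc but no phylogeny-aware null is
  provided.
* Pivotless enumeration is exponential on large dense conserved modules
  (see above); cohorts of STRING scale require patience or a scaled-down
  COG universe.
* The synthetic noise model is uniform and uncorrelated; see the
  synthetic-cohorts section for what that implies about test evidence.
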