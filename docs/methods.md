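# Methods

This note documents the models, algorithms, numerical choices, and study
protocols implemented in `congruphy`, and what the synthetic-data tests do
and do not demonstrate.

## Trees and bipartitions

Trees are stored rooted (node objects with children lists), but every
congruence metric treats them as unrooted: quartets and bipartitions are
properties of the unrooted topology, so rooting (by convention on the
outgroup) affects only display and serialization.  A bipartition is stored
canonically as the block *not* containing the lexicographically smallest
leaf; trivial splits are excluded everywhere.  Pruning always suppresses
degree-2 nodes, merging branch lengths.  Strict and majority-rule consensus
are computed by split counting followed by reconstruction of the tree from
the retained (necessarily laminar) block family; dendropy's consensus is
used in the test suite as an independent cross-check, never as the
implementation.  Serialization orders children lexicographically so that
equal topologies print identically.

## Parsimony

**Fitch scoring.** Character states are encoded as bitmasks over each
column's observed alphabet; missing (`?`) and inapplicable (`-`) cells carry
the full alphabet mask.  The downpass combines children by iterated pairwise
intersection/union, vectorized with numpy across all characters at once, so
one tree evaluation costs a handful of array operations per node.  On
polytomies the iterated pairwise rule can overcount relative to the exact
unit-cost minimum; the exact dynamic programme (below) is available via
`fitch_length(..., exact=True)` and is what ancestral-state reconstruction
uses.  Search trees are always binary, where the two coincide.

**Implied weights.** The concave fit is `Σᵢ eᵢ/(eᵢ+k)` with
`eᵢ = stepsᵢ − minᵢ`, where `minᵢ` counts one step per extra state observed
unambiguously (singleton cells) among the scored taxa.  This differs from
TNT's fit by an additive per-character constant and therefore induces the
same tree ranking; the ranking converges to equal weights as `k → ∞`
(asserted as a monotonicity property in the tests).

**Search.** Exhaustive enumeration (all unrooted topologies by sequential
insertion) is automatic at ≤ 8 taxa and returns the complete optimum set.
The heuristic uses random-addition-sequence starting trees (greedy stepwise
insertion, ties broken randomly from the seeded generator), steepest-descent
NNI to a local optimum, optional SPR rounds (`swap="spr"`), and collects
equal-score NNI neighbours of each local optimum (up to `tie_neighbors`) so
that the strict consensus of co-optima is meaningful.  All retained trees
are deduplicated by canonical topology string, capped at `max_trees`
(10,000).  NNI is the default swap because the experiment batteries run
hundreds of searches; SPR is noticeably stronger on rugged random matrices
and is used wherever a single search must hit the exact optimum.

**Ancestral states.** Reconstruction runs an exact unit-cost Sankoff-style
dynamic programme over (characters × states), correct on polytomies, plus an
"outside" pass giving, per node and state, the optimal cost of the rest of
the tree; a state is in a node's MPR set iff inside + outside cost equals
the optimum.  Resolutions: at the root both modes tie-break to the
lexicographically smallest optimal state; below it, given the parent's
resolved state *p*, the conditional optimum set is
`argminₓ [C(v,x) + 1(x≠p)]` — **deltran** keeps *p* whenever it is in that
set (changes as late as possible), **acctran** prefers a non-*p* member when
one exists (changes as early as possible).  Any such preorder choice
realizes the minimum change count, which the tests verify exhaustively
against Fitch lengths on small binary-character instances.

**Hypothetical ancestors.** One terminal row per internal node (preorder
numbering, root = node 1) of a reference topology, which may contain
polytomies.  Cells carry the mode's conditional optimum set (ambiguity sets
exported as polymorphic cells; the root keeps its full optimum set).  A
character is exported INAPPLICABLE when all of the node's descendant leaves
are inapplicable and MISSING when no descendant observed it.  Re-attaching
every exported ancestor beside its node leaves the tree's parsimony score
unchanged — they are most-parsimonious interpolations, asserted in tests.

## Congruence metrics

`quartet_status_counts` classifies all `C(n,4)` quartets by scanning each
tree's split matrix (a boolean splits × leaves array): a quartet `ab|cd` is
resolved by a split separating `{a,b}` from `{c,d}`.  The scan is vectorized
over quartets and exact; the test suite checks it against four-point-
condition enumeration on hundreds of random (including multifurcating) tree
pairs.  From the five-way counts:

* quartet divergence `(2d + r₁ + r₂)/2Q` — a quartet resolved in only one
  tree carries half the penalty of outright conflict, which operationalizes
  normalization "against the maximum information attainable"; raw counts are
  always exposed so any alternative normalization can be recomputed;
* shared-quartet proportion `s/(s + d + r₂)` — reference-normalized, hence
  asymmetric; quartets the reference leaves unresolved (its polytomies) drop
  out of the denominator by construction;
* Robinson–Foulds: raw symmetric split difference, and scaled by the test
  tree's resolution fraction (its non-trivial split count over `n − 3`); a
  star test tree has no defined scaled value and raises;
* shared partitions on unrooted splits, with a rooted-clade variant exposed
  because clade-counting tools differ in whether they respect the root.

## Experiments

Each replicate: build the replicate matrix, run `mp_search`, take the strict
consensus of retained co-optima (never a single arbitrary optimum), prune
consensus and reference to common taxa, compute all metrics.  Per-replicate
seeds derive from the master seed via `numpy.random.SeedSequence` with a
(level, arm, replicate) path, so any slice of an experiment can be rerun
independently and the whole record set is bit-reproducible.

*Site resampling*: for each sampling fraction, DNA+indel columns are drawn
jointly without replacement (round-half-up counts); the two arms of a
replicate are **paired** — the same site draw analysed with and without the
full, unsubsampled morphology partition — which removes site-draw noise from
the arm contrast.  *Taxon addition*: N pool members drawn without
replacement per replicate, morphology-only search on base ∪ drawn.  Trend
summaries are ordinary least squares of metric on condition (slope, adjusted
R², slope p-value) over all records, plus per-level mean ± SD for plotting;
paired t and Wilcoxon variants of the arm comparison are exposed without
asserting a preferred one.

## Synthetic data

The generator emulates the structure of a genus-level total-evidence study
of a mammalian clade; defaults mirror that design (60 extant taxa with a
41-taxon well-corroborated core, 42 fossils, 219 morphological characters,
15,407 DNA sites + 188 binary indels).  Its components, with the defaults
and the reasoning:

* **Tree shape**: birth–death (birth 1.0, death 0.5), ultrametric, height
  normalized to 1. Every extant terminal branch is stretched by 0.35 before
  renormalization: sampling one genus per lineage leaves each sampled tip far
  from its last common ancestors, the long extant root-to-tip paths that
  fossils break up.
* **Reference tree**: the true tree restricted to the core subset with 10%
  of internal edges collapsed to polytomies (an incompletely resolved
  consensus of independent genomic evidence).
* **Non-core extant taxa** get a ×4 terminal-branch multiplier: in practice
  the lineages a well-corroborated reference omits are the unstable,
  long-branched ones.
* **Characters**: symmetric Mk per character (morphology 2–4 states drawn
  with weights 0.6/0.25/0.15, DNA 4-state, indels binary), discretized-gamma
  (4 categories, shape 0.5) rate multipliers.  Morphology rate 1.0 and DNA
  rate 2.0 expected substitutions per unit height: a saturating,
  mitochondria-heavy alignment next to conservative hard-tissue characters,
  which is what makes adding morphology valuable at every molecular sampling
  level.
* **Convergence**: 30% of morphology characters are convergence-prone; each
  taxon belongs to one of 3 "ecomorph" syndromes and is pulled to its
  syndrome's target state with probability `1 − exp(−0.4 · tip²)`
  (tip = terminal branch length).  Convergent adaptation accrues — and
  accelerates — with time spent on a terminal branch, so long-tipped extant
  taxa are heavily affected while fossils and densely sampled core taxa
  largely escape it.  This is the mechanism by which added extant
  morphology degrades congruence.
* **Molecular rogues**: 2 core taxa evolve DNA on ×4-length tips — a
  persistent long-branch artefact in molecular-only parsimony that
  morphology can correct.
* **Fossils**: attach to an edge spanning a target depth drawn uniformly on
  (0, 0.7) × height, with terminal branches 0.05 × the mean extant terminal
  branch (jittered ±50%) — temporal proximity to common ancestors as short
  root-to-tip paths.
* **Missingness**: missing-at-random per cell — 5% for extant morphology,
  +17% for fossils (matching a well-preserved skeleton codable for ~83% of
  characters), 2% inapplicable cells in morphology; DNA and indels are
  entirely missing for fossils.

What the generator does **not** emulate: correlated character evolution
beyond the ecomorph pulls, block-wise missingness of whole anatomical
regions (a block-missing switch exists for robustness checks but is off by
default), alignment error, among-site compositional bias, and real
fossilization biases.  Passing tests therefore show that the pipeline
recovers these phenomena *when the data contain them by construction*, not
that any real dataset must behave this way.

## Desk-scale protocols (tests and the acceptance script)

Chosen once as the package's own scaled-down study, to keep the full battery
within minutes:

* *Oracle equivalence*: 200 random tree pairs (n ≤ 12) for quartet counts;
  150 random (tree ≤ 7 leaves, ≤ 3-state character) instances for Fitch;
  4 random matrices (7–8 taxa) where heuristic SPR search must match the
  exhaustive optimum.
* *Site resampling*: 3 datasets × (20 core extant, 150 morphology, 1,200
  DNA + 30 indels) × 6 levels (2–90%) × 10 paired replicates.  Morphology's
  column share is kept small, as in the motivating design, but large enough
  that its corrective signal on the molecular rogues dominates its sampling
  noise.  Expected pattern: congruence rises monotonically with sampling
  (Spearman), and the with-morphology arm's mean quartet divergence is ≤ the
  without-arm's at every level.  The per-level contrast at the 90% level is
  small (~0.01) and noise-limited; for some master seeds a pooled run can
  show 5/6 advantage levels.
* *Taxon addition*: 8 datasets × (21 extant / 15 core / 12 fossils, 150
  morphology characters); fossils and hypothetical ancestors added to the
  full extant base, extra extant taxa added to the core base (mirroring the
  two designs of the motivating study — the fossil trend from a core-only
  base is reported there as non-monotonic), counts {0,3,6,9,12} × 3
  replicates, records pooled across datasets before the OLS fit.  Expected:
  slope(ancestors) ≤ slope(fossils) ≤ 0 < slope(extant) for quartet
  divergence vs N added.
* *End-to-end*: one full-size dataset (41 core + 19 other extant + 20
  fossils; 219 morphology + 4,000 DNA), 2-replicate NNI search; the
  combined-data consensus restricted to the core shares ≥ 0.9 of the
  reference's resolved quartets at the fixed test seed (seed-to-seed range
  roughly 0.82–0.92, dominated by how badly the two molecular rogues
  misbehave).

## Numerical choices and degenerate inputs

Score comparisons use an absolute tolerance of 1e-9 (implied-weights scores
are floats); site counts round half-up; subsampling is without replacement;
all-missing taxa are retained in searches (they join consensus trees as
unresolved placements); a star test tree raises on resolution-scaled RF and
a reference that resolves nothing raises on the shared-quartet proportion
(the experiment layer records these as missing rather than failing the
replicate); duplicate labels, leaf-set mismatches, fractions outside (0,1],
non-positive concavity constants, and degenerate roots raise typed errors
(`TreeError`, `MatrixError`, `ParsimonyError`, `MetricError`,
`ExperimentError`, `SimulationError`).

## Known limitations

* The iterated-pairwise Fitch downpass on polytomies is the classical
  approximation; exact polytomy handling exists only on the reconstruction
  path.
* TBR swapping is not implemented; SPR is the strongest available move set.
* Implied-weights search uses the same swap machinery as equal weights but
  recomputes full scores per rearrangement (no incremental update), so very
  large matrices are slow under heuristic search.
* The quartet classifier is O(splits × quartets); fine to ~60 taxa, not
  intended for hundreds.
* Hypothetical-ancestor export assumes the reference topology is correct;
  ambiguity sets make re-analysis conservative but cannot express
  between-character correlation of the underlying reconstructions.
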