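# Methods

This note documents the statistical model, the algorithmic choices, and the
limits of what the synthetic experiments demonstrate.

## Hypothesis language and rule semantics

The search space is the set of conjunctions containing at most one term
literal per ontology branch (BP, MF, CC, KEGG) and at most one interaction
literal. KEGG pathways are modelled as a flat branch (a root with leaf
pathways) inside the same ontology structure, so one search mechanism
serves all four vocabularies. Only the `is_a` and `part_of` relations are
used, and both propagate annotations identically (true-path rule: a gene
annotated to a term is annotated to all its ancestors).

A term literal covers the term's propagated gene set. The interaction
literal INT(t) covers every gene with a *recorded* interaction partner in
the propagated set of t; a gene is not its own witness unless a self-pair
is explicitly listed. The extension of a conjunction is the intersection of
its literals' sets, restricted to the annotation universe. INT wraps a
single term, never a sub-conjunction, and at most one INT literal is
allowed — this matches the shape of every rule the method is meant to
output ("term ∧ interacting with term") and keeps the space finite and
interpretable.

Genes are opaque, case-sensitive strings after synonym resolution; the
synonym map is applied entrywise (never transitively), and chains that loop
with length > 1 are rejected rather than silently resolved.

## Search: level-wise refinement with anti-monotone pruning

Coverage is anti-monotone: replacing a term by a descendant, or adding a
literal, can only shrink a rule's extension. The enumerator exploits this
with an Apriori-style level-wise scan: conjunctions are generated
shortest-first, terms parents-before-children within each slot, and a
conjunction is evaluated only after *all* of its one-step generalizations
(drop a literal; replace a term by its nearest unfiltered ancestor) are
known viable. A conjunction below `min_set_size` is marked pruned and so,
transitively, is everything that specializes it — no specialization of a
pruned conjunction is ever evaluated, a property the test suite asserts
with an instrumented recorder. `max_set_size`, in contrast, only filters
output: a too-large extension may shrink into range under specialization,
so pruning on it would sacrifice completeness.

Terms removed from the hypothesis language (blocklist of overly general
terms, or a `max_genes` cap on propagated set size) stay out of candidate
generation but remain *transparent*: their children are still reachable,
and their genes stay in the universe, because filtering shapes the
description language, not the statistical background.

Output order is deterministic: rules sort lexicographically by (slot,
ontology file position) of their literals, with slots ordered BP, MF, CC,
KEGG, INT. `count_search_space` reports the size of the raw combination
space — a product of (branch size + 1) over enabled branches, times
(1 + number of INT inner terms), minus the empty combination — as a
pre-flight cost estimate; it deliberately ignores both the coverage filter
and `max_literals`.

## Gene-level statistics

The expression matrix is assumed normalized and log2-scale; logFC is the
difference of class means (class A minus class B, where A is the first
class of a user-declared ordering), so it is additive and matches
microarray convention.

Ranking uses Welch's t by default (a pooled-variance flag exists); a gene
with zero variance in both classes scores 0 when the means are equal and
±∞ otherwise, which sorts it to the extremes rather than erroring. ReliefF
is implemented in its canonical numeric-feature form: samples are
instances, genes are features min-max normalized to [0, 1], instance
distance is Manhattan, and each sampled instance moves every feature weight
down by its mean difference to the k nearest hits and up by its mean
difference to the k nearest misses. With `n_iterations` at least the sample
count every instance is used exactly once, making the estimate
deterministic. All ranking ties break by stable sort on input order.

`split_up_down` assigns zero-logFC genes to neither list — they are neither
up- nor down-regulated.

## Enrichment tests

Before scoring, the annotation universe is intersected with the ranked
gene list, so the statistical background equals the measured universe.

* **Fisher** — one-sided over-representation: the hypergeometric tail
  probability of observing at least the actual overlap between the rule's
  genes and the top-k ranked genes, with the remaining genes as background
  (the classic "top 1000 vs the rest" design).
* **GSEA** — classic unweighted enrichment score: walking the ranked list,
  the running sum gains 1/m at rule genes and loses 1/(N−m) elsewhere; the
  ES is the deviation of maximal absolute value (ties between the positive
  and negative extreme resolve to the positive). The empirical p-value is
  (r + 1)/(B + 1) over B gene-label shuffles, two-sided on |ES|. The
  add-one form never returns zero.
* **PAGE** — z = (S̄ₘ − μ)·√m/δ, with μ and δ the mean and sample standard
  deviation of all gene-level logFC values and S̄ₘ the rule-gene mean;
  two-sided normal tail. logFC (not the ranking score) feeds GSEA's order
  statistics and PAGE, following PAGE's fold-change formulation; the
  ranking statistic's only statistical role is defining the top-k cut.

The aggregate p is the weighted arithmetic mean Σwᵢpᵢ/Σwᵢ (equal weights by
default). It is a ranking heuristic for "small on several tests
simultaneously", not a calibrated tail probability, which is why the
family-wise correction below is computed on the permutation distribution of
the aggregate itself rather than on any parametric reference.

## Multiple-testing correction

The primary correction is permutation-based, maxT-style: for each of B
seeded gene-label shuffles of the ranked list, every candidate rule is
rescored with the full three-test procedure and the minimum aggregate p is
recorded; a rule's corrected p is (#{null minima ≤ its aggregate p} + 1) /
(B + 1). Gene-label shuffling (rather than class-label shuffling) is the
scheme implementable from a ranked list alone — it avoids re-running the
ranking inside the loop — and is applied identically to all three tests.
This is a known divergence risk against class-label permutation: it
preserves the gene-set size structure and the between-rule correlation but
treats the observed ranking as fixed. Bonferroni and Benjamini–Hochberg FDR
are available as cheaper alternatives.

Two implementation notes. First, under gene-label shuffling the hit
positions of a size-m set are a uniform random m-subset of ranks, so the
GSEA null |ES| distribution depends only on (N, m); the scorer draws one
seeded null sample per set size and reuses it across rules and outer
permutations. The stand-alone `gsea_p` function draws fresh permutations
per call; both implement the same estimator. Second, rule rescoring inside
the permutation loop is vectorized (one flat index array with segment
reductions per permutation) and is bit-consistent with the scalar per-rule
path up to ~1 ulp in the PAGE mean.

All randomness descends from a single integer seed via numpy
`SeedSequence` spawn keys, making every pipeline run bit-reproducible.

## Rule clustering and comparison

Significant rules are encoded as binary membership vectors over the gene
universe — the only encoding consistent with clustering "by similarity of
gene sets". Distances: Euclidean (=√Hamming on binaries), Manhattan
(=Hamming count), Hamming, and Jaccard. A "Relief" inter-rule distance is
sometimes named alongside these but has no citable definition for sets; it
is deliberately not implemented, and Jaccard is offered as the
clearly-defined alternative.

Agglomeration uses Lance–Williams updates for single, complete, average and
Ward linkage. Ward is restricted to Euclidean input (its variance
interpretation requires Euclidean geometry) and its heights follow the
√(2·ΔESS) convention, matching scipy. Merges are deterministic: the pair at
minimal distance merges, with ties — including distances equal up to
1e-9 relative floating-point round-off, which arise whenever two binary
vectors are equidistant — broken by the smallest pair of original rule
indices. Cutting the dendrogram at k undoes the last k−1 merges and labels
clusters 1..k by smallest member index; the k-cut provably refines the
(k−1)-cut. Per-cluster unions and intersections of the member gene sets
summarize each cluster.

Rule-vs-reference comparison is the coverage matrix v(i,j) = |Sᵢ ∩ Dⱼ| /
|Dⱼ| ∈ [0, 1]: how much of reference set j the rule i covers. Filtering
general terms before the search matters here — an unfiltered root-level
rule would trivially cover every reference set.

## Synthetic data generator

The generator emulates the structure the method assumes: per branch a
rooted `branching_factor`-ary tree of terms (with occasional extra
`part_of` parents to make it a proper DAG), genes annotated independently
to each leaf with probability `annotation_rate` and propagated upward, a
uniform random interaction network, and per-gene baselines (uniform on
[6, 10] log2 units) plus i.i.d. Gaussian noise. A planted rule's TERM
literals are co-annotated with a shared random gene set of
`planted_set_size` genes, and the planted extension gains `effect_size`
log2 units in class A only. INT literals may appear in a planted rule but
receive no extra interactions.

Default study conditions: 500 genes, 15 terms per branch, annotation rate
0.05, 300 interactions, 6 samples per class, noise SD 0.5 and effect 1.5
(an effect-to-noise ratio of 3, i.e. a strong ~3-fold expression change
against typical within-class variability, detectable but not trivial at
n = 6 per class). The calibration experiments use two reduced designs: a
null design (120 genes, two branches of 7 terms, effect 0) small enough to
replicate 200 times for the type-I error check, and the default design with
a planted two-literal rule for the 50-replicate recovery check. Recovery
accepts generalizations of the planted rule (ancestor terms, dropped
literals) because ancestors cover supersets of the planted genes and can
legitimately score as well.

What the generator does **not** emulate: probe effects, intensity-dependent
variance, correlated noise between genes, annotation bias toward
well-studied genes, and scale-free interaction topology. Passing the
calibration experiments therefore shows the machinery is correct and
calibrated under exchangeable Gaussian noise, not that real-data
discoveries at α = 0.05 carry exactly that error rate.

## Numerical choices and degenerate inputs

* Empirical p-values use the add-one rule everywhere; the smallest
  attainable corrected p is 1/(B + 1).
* Fisher's test caches the hypergeometric tail per set size; PAGE uses
  `erfc` for the normal tail (equal to the scipy normal survival function
  to full precision, asserted in tests).
* A rule covering no ranked genes, or all of them, is a scoring error;
  candidate generation prevents both via `min_set_size` and the universe
  restriction.
* Degenerate gene-level scores (zero logFC variance) abort PAGE with an
  explicit error rather than returning 0/0.
* Welch zero-variance handling is described under gene-level statistics;
  obsolete ontology terms are skipped at parse time; parse errors name the
  offending line; cycles in the term graph or the synonym map are reported
  with the cycle itself.

## Known limitations

* Class-label permutation (re-ranking inside the loop) is not implemented;
  the gene-label scheme is the documented stand-in.
* No normalized enrichment score (NES): set-size adaptivity comes from the
  per-size null sample instead.
* The search is exhaustive within its bounds; there is no beam or heuristic
  mode, so very deep ontologies with permissive `min_set_size` can be
  expensive (the anti-monotone pruning is the only cost control).
* Duplicate-coverage rules with different descriptions are all kept by
  design — clustering, not deduplication, is the redundancy handling.
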