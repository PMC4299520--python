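# Methods

## The distributed gene order distance

The statistic treats a prokaryotic chromosome as a circular sequence of
gene ranks. For a genome pair with a one-to-one ortholog map, one Monte
Carlo draw selects `k_genes` ortholog pairs uniformly without
replacement; the draw is **valid** only if every pair of selected genes
is separated by at least `min_gap` positions (circular index distance,
`min(|i−j|, L−|i−j|)`) in *both* genomes, and the raw distance D is the
fraction of valid draws in which the k orthologs are *not* in the same
circular order in the two genomes. Order is compared up to rotation and
reflection: the origin of a circular chromosome and its reading direction
are both arbitrary, and gene orientation (strand) is ignored.

Key consequences of this design:

* The spacing rule makes the statistic blind to rearrangements shorter
  than `min_gap` — sets of adjacent genes (operons) cannot dominate the
  sample, and local scrambling below the gap scale is invisible.
* For k labels there are (k−1)!/2 circular arrangement classes: m = 60
  for k = 6 and m = 12 for k = 5. Under random order the order test
  passes with probability 1/m, so D saturates at (m−1)/m — 59/60 ≈
  0.9833 for six genes.

Draws rejected for spacing are redrawn and **not** counted toward n, so D
is a proper conditional frequency over spacing-valid subsets. If a probe
of 10,000 candidate subsets accepts fewer than 0.1%, the genome pair is
reported as unsatisfiable rather than ground through.

The five-gene variant (`k_genes=5`) may be run either with its natural
constant m = 12 (`m_constant="auto"`) or with the six-gene constant
(`m_constant="fixed:60"`); with m = 60 the logarithmic correction is
numerically within 2% of the plain D′ = −ln(1−D) for D ≤ 0.75 (about 6%
at D = 0.9), which is the sense in which that variant is functionally the
simple logarithmic correction.

## Corrections

All corrections are monotone in D, vanish at D = 0, and agree with D to
first order.

* **Adapted Jukes–Cantor** (`jc`): −((m−1)/m)·ln(1 − (m/(m−1))·D).
  Models order divergence as exponential approach to the uniform
  distribution over the m arrangement classes. Undefined (NaN) for
  D ≥ (m−1)/m; callers decide the fallback.
* **Tajima series** (`tajima`): Σ_{i=1..k} k⁽ⁱ⁾ / (i·((m−1)/m)^{i−1}·n⁽ⁱ⁾)
  with falling factorials k⁽ⁱ⁾ = k!/(k−i)!. This moment-series analogue
  of the logarithm is finite for every k ≤ n — its purpose is to keep
  near- and beyond-saturation pairs in the analysis. Terms are generated
  by the exact recurrence t_{i+1} = t_i·((k−i)/(n−i))·(i/(i+1))·(m/(m−1))
  and truncated when a term falls below 1e−12 of the running sum (terms
  decay geometrically for D below saturation).
* **Simple logarithm** (`logcorr`): D′ = −ln(1−D), undefined at D ≥ 1.

Pooling across replicates sums the integer counts (k_fail, n) per pair
*before* correcting — the correction of pooled counts, not the mean of
per-replicate corrections.

## Sampling schedule and reproducibility

The production schedule is `n_replicates=100` × `n_iter=100,000` valid
draws per pair (10⁷ pooled). Every (genome pair, replicate) gets an
independent RNG stream seeded by `SeedSequence([seed, crc32(id_a),
crc32(id_b), replicate])` with the pair ids sorted, so results are
independent of pair evaluation order, replicates are independent, and
identical inputs are bit-identical. The sampler is vectorized in batches
of 16,384 attempted draws; validity and truncation are applied in attempt
order so multi-replicon genomes are not biased when a batch overshoots
`n_iter`.

Multi-replicon genomes: the default `replicon_mode="largest"` restricts
both genomes to their largest replicon (lexicographic tie-break). In
`per-replicon` mode a draw first selects a replicon pair with probability
proportional to its co-resident shared-ortholog count, then draws all k
orthologs there. Linear (non-circular) replicons are compared without
rotation freedom — only reflection — and spacing uses linear distance.

An exhaustive oracle (`exact_raw_distance`) enumerates every
spacing-valid k-subset (budget 10⁷ subsets) and returns the exact
expectation the sampler estimates; the test suite checks the sampler
against it within 3 standard errors and against an independent
plain-Python enumeration.

## Tree layer

* **Neighbor joining** is the standard Saitou–Nei agglomeration with the
  Q criterion, implemented in-package so ties are deterministic: ties in
  Q break by the lexicographically smallest (cluster label, cluster
  label) pair, a cluster's label being its smallest member taxon.
  Negative branch-length estimates are clamped to zero with the deficit
  moved to the sibling branch. Cross-checked against scikit-bio's NJ.
* **Robinson–Foulds** distances and restrictions operate on bipartition
  sets: the splits of a tree restricted to a taxon subset are exactly the
  non-trivial intersections of its splits with the subset, so no explicit
  pruning is needed. Fewer than four shared taxa is signalled as
  undefined.
* **Midpoint rooting** places the root halfway along the longest
  leaf-to-leaf path; ties break by the lexicographically smallest
  endpoint pair, and an all-zero-length tree is an error.
* **Replicate support** annotates each internal edge of a reference tree
  (built from the pooled matrix) with the number of replicate trees
  containing the same bipartition. This is replicate resampling of the
  Monte Carlo estimator, not a data bootstrap: it measures sampling
  noise of the distances, not robustness to data removal.

## Agreement subtrees

An agreement set is a taxon subset on which all input trees, restricted,
share one topology. Maximum agreement across >2 trees is NP-hard, so the
package ships two routes: an exhaustive search (largest subset size
first, all maximum sets returned) refused above 20 common taxa, and a
greedy heuristic that repeatedly removes the taxon whose removal most
reduces total pairwise split disagreement (lexicographic tie-break) until
agreement holds. The heuristic returns *an* agreement set, not
necessarily a maximum one; on ≤12-taxon instances the suite checks it
stays within two taxa of the exact optimum.

## Hierarchical ranked-pair tree building

Short gene-order distances are estimated far more reliably than
near-saturated ones. The builder ranks all pairs by ascending distance
(lexicographic tie-break, undefined entries last) and walks down the
list, maintaining the graph of admitted pairs. When the newly admitted
pair completes a clique of ≥4 taxa (NJ needs a complete submatrix —
cliques are the minimal faithful notion of "enough pairwise distances"),
an NJ tree is built on the clique; it is rejected if its restricted
topology conflicts (RF > 0 on ≥4 shared taxa) with any retained tree,
absorbs retained trees it contains, and is then merged with compatible
neighbours by rebuilding NJ on union taxon sets, keeping a union only if
both original backbone topologies survive restriction. Only cliques
containing the newly admitted pair are examined at each rank. A second
phase visits outside taxa in order of their best ranked distance to a
tree member and accepts an addition only when the prior topology is
unchanged. All tie-breaks are specified, so the ledger is deterministic.

## The rearrangement simulator

`simulate` evolves a circular gene order by inversions (segment reversal
with strand flip) and optionally transpositions; gene content is
conserved exactly, so the identity map on gene ids is a correct ortholog
map between any two descendants — the simulator models pure
rearrangement, not gene gain/loss, duplication or transfer. Segment
lengths are uniform on 1..L/2 (the default, reflecting the large
inversions common between closely related prokaryotes) or geometric.

What the simulator does and does not establish: passing the recovery
tests shows the estimator and tree machinery behave correctly when their
model assumptions hold (one-to-one orthologs, content conservation,
homogeneous rates). Real genomes violate several of these — orthology
calls are noisy, content changes, rearrangement rates and hotspots vary —
so synthetic recovery rates do not transfer to real data.

### Recovery experiment conditions

The parameter-recovery acceptance experiment uses a fixed balanced 8-leaf
tree with all branch lengths 1.0, a 1,000-gene root, inversion-only
events with geometric(0.1) segment lengths (mean 10 genes), 100 events
per unit branch length, and 10,000 valid draws per pair. These sizes keep
the full 20-seed experiment near a quarter minute while leaving ample
statistical margin. The event regime matters and was chosen on first
principles: segments shorter than `min_gap` are invisible to the
statistic, while few large (uniform-length) inversions make D a
high-variance clock — each event relocates a sizeable random fraction of
the genome, so two runs with the same event count can differ in D by tens
of percent. Many medium-length inversions average that noise away.
The corrected distance is also systematically sub-additive along paths
(the m-class shuffle model only approximates inversion dynamics), which
NJ tolerates but which degrades recovery on trees with strongly unequal
branch lengths.

## Numerical and degenerate-input choices

* Tajima truncation: relative term < 1e−12.
* RBH "best" is the bitscore, descending; exact-equality ties disqualify
  the query (deterministic and conservative).
* Gene-content similarity S uses genome-wide gene counts after exclusion
  masks, not replicon-restricted counts: content and order are separate
  measures.
* Matrix symmetry is validated exactly; NaN marks entries where a
  correction left its domain, and NJ refuses matrices containing them.
* `min_gap` is an index separation: "at least 5 genes away" means
  separation ≥ 5, i.e. at least 4 intervening genes, in both genomes.

## Known limitations

* The heuristic agreement search has no optimality guarantee; exact
  search is exponential and capped at 20 taxa.
* The hierarchical builder examines only cliques containing the newest
  pair; an alternative reading (re-examining all cliques at every rank)
  would be slower and, on additive inputs, equivalent.
* Tajima-corrected values beyond saturation are finite but extremely
  noisy; trees built from them should be read with the replicate support
  in hand.
* The estimator assumes the ortholog map is one-to-one and position-true;
  paralog confusion appears as spurious order divergence.
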