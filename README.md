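# geordi

**Distributed gene order distances and gene-order phylogenetics for
circular prokaryotic genomes.**

Gene order decays fast in prokaryotes — single inversions can span half a
chromosome — yet residual order conservation carries phylogenetic signal
between even distantly related groups. `geordi` measures that signal with
a Monte Carlo statistic and turns the resulting distance matrices into
trees.

## The statistic

For a pair of genomes with a one-to-one ortholog map, repeatedly:

1. draw *k* ∈ {5, 6} ortholog pairs uniformly at random, requiring every
   chosen gene to lie at least `min_gap` (default 5) positions from every
   other along the chromosome **in both genomes** (so a single operon
   cannot be sampled twice);
2. test whether the *k* orthologs appear in the same circular order in
   both genomes, up to rotation and reflection (gene orientation and the
   arbitrary origin/strand of a circular chromosome carry no information).

The raw distance *D* is the fraction of draws failing the order test.
Because six labels admit only *m* = (6−1)!/2 = 60 distinct circular
arrangements, *D* saturates at (m−1)/m = 59/60 ≈ 0.983 as order
randomizes. Three corrections map *D* to an additive divergence:

* adapted Jukes–Cantor: D_JC = −(59/60)·ln(1 − (60/59)·D), finite only
  for D < 59/60;
* Tajima's falling-factorial series on the raw counts (k, n), finite for
  every k ≤ n, so saturated pairs stay in the analysis;
* the simple D′ = −ln(1 − D).

Downstream, the package assembles replicate distance matrices (100
replicates × 100,000 draws, pooled to 10⁷ draws per pair, by default),
builds neighbor-joining trees with per-edge replicate support, computes
agreement subtrees across replicate trees (exact on small instances, a
greedy heuristic at scale), and offers a hierarchical ranked-pair tree
builder that grows trees from the shortest (best-estimated) distances
outward. A rearrangement simulator (inversions/transpositions along a
tree) generates test data with known truth, and gene-content distances
(−ln S) plus distance-matrix correlation support method comparisons.

## Worked example

Simulate eight genomes along a balanced tree, estimate all pairwise
distances, and rebuild the phylogeny:

```python
import geordi as g

tree = g.PhyloTree.from_newick(
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
root = g.random_genome(1000, "root", seed=0)
model = g.RearrangementModel(segment_length="geometric:0.1",
                             events_rate=100.0)
genomes, _ = g.evolve_along_tree(tree, root, model, seed=0)

cfg = g.SamplerConfig(k_genes=6, min_gap=5, n_iter=10_000, seed=0)
estimates = []
for i, a in enumerate(genomes):
    for b in genomes[i + 1:]:
        om = g.identity_orthomap(a, b)
        estimates.append(g.sample_raw_distance(a, b, om, cfg))

ab = next(e for e in estimates if set(e.genome_pair) == {"A", "B"})
ah = next(e for e in estimates if set(e.genome_pair) == {"A", "H"})
print(f"D(A,B) = {ab.D:.3f}   D(A,H) = {ah.D:.3f}")

mat = g.assemble_matrix(estimates, correction="tajima", m=60)
rec = g.nj_tree(mat)
print("RF distance to the true tree:", g.rf_distance(rec, tree))
```

Output:

```
D(A,B) = 0.175   D(A,H) = 0.334
RF distance to the true tree: 0
```

Sister taxa A and B (two branches apart) show much less order divergence
than A and H (six branches apart), and neighbor joining on the
Tajima-corrected matrix reconstructs the generating topology exactly.

The same analysis runs from the shell via the `geordi` CLI
(`simulate`, `rbh`, `distance`, `matrix`, `nj`, `support`, `mast`,
`hierarchical`, `correlate`, and `run` for a YAML-configured end-to-end
pipeline with a reproducibility manifest).

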