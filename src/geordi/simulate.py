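"""Synthetic genome evolution by rearrangement.

Generates circular genomes and diverges them by inversions (segment
reversal with strand flip) and optionally transpositions (segment excision
and reinsertion).  Gene content is conserved exactly — the generator models
pure rearrangement, not gain/loss — so the identity map on gene ids is a
valid ortholog map between any two genomes descended from the same root.
Inversion is the default and dominant event, reflecting the rearrangement
spectrum observed between closely related prokaryotes, where inversions
spanning up to half the chromosome are common.

Also provides additive (path-length) distance matrices and random binary
trees as oracles for the tree algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_model import GeneLocus, GenomeRecord, OrthologMap, Replicon


@dataclass(frozen=True)
class RearrangementModel:
    """Event mix and segment-length law for genome rearrangement.

    ``segment_length`` is ``uniform`` (1 .. L/2) or ``geometric:<p>``;
    ``events_rate`` scales Poisson event counts per unit branch length in
    `evolve_along_tree`.
    """

    inversion_weight: float = 1.0
    transposition_weight: float = 0.0
    segment_length: str = "uniform"
    events_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.inversion_weight < 0 or self.transposition_weight < 0:
            raise ValueError("event weights must be ≥ 0")
        if self.inversion_weight + self.transposition_weight == 0:
            raise ValueError("at least one event weight must be positive")

    def _segment_len(self, rng: np.random.Generator, L: int) -> int:
        if self.segment_length == "uniform":
            return int(rng.integers(1, max(2, L // 2 + 1)))
        if self.segment_length.startswith("geometric:"):
            p = float(self.segment_length.split(":", 1)[1])
            return int(min(rng.geometric(p), max(1, L - 1)))
        raise ValueError(f"unknown segment_length {self.segment_length!r}")


def random_genome(
    n_genes: int, genome_id: str = "g", seed: int = 0
) -> GenomeRecord:
    """A single circular replicon with genes g0..g{n−1} in index order and
    random strands."""
    if n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")
    rng = np.random.default_rng(seed)
    strands = rng.choice(["+", "-"], size=n_genes)
    loci = [
        GeneLocus(gene_id=f"g{i}", replicon_id="chr", index=i, strand=strands[i])
        for i in range(n_genes)
    ]
    return GenomeRecord(genome_id=genome_id, replicons=[Replicon("chr", loci)])


def shuffled_copy(
    genome: GenomeRecord, genome_id: str, seed: int = 0
) -> GenomeRecord:
    """Same gene content in a uniformly random circular order — the
    saturation control (infinite-divergence limit)."""
    rng = np.random.default_rng(seed)
    replicons = []
    for rep in genome.replicons:
        perm = rng.permutation(len(rep))
        loci = [
            GeneLocus(
                gene_id=rep.loci[j].gene_id,
                replicon_id=rep.replicon_id,
                index=i,
                strand=rep.loci[j].strand,
            )
            for i, j in enumerate(perm)
        ]
        replicons.append(Replicon(rep.replicon_id, loci, circular=rep.circular))
    return GenomeRecord(genome_id=genome_id, replicons=replicons,
                        excluded_genes=set(genome.excluded_genes))


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, "?")


def apply_events(
    genome: GenomeRecord,
    model: RearrangementModel,
    n_events: int,
    seed: int = 0,
    genome_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> GenomeRecord:
    """Apply ``n_events`` sampled rearrangements to (a copy of) the genome.

    An inversion reverses a contiguous circular segment and flips the
    strands inside it; a transposition excises a segment and reinserts it
    at a random other position.  Gene content is unchanged.  Events act on
    the largest replicon of multi-replicon genomes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    replicons = list(genome.replicons)
    target = max(range(len(replicons)), key=lambda i: len(replicons[i]))
    rep = replicons[target]
    order = [(g.gene_id, g.strand) for g in rep.loci]
    L = len(order)
    w = np.array([model.inversion_weight, model.transposition_weight])
    w = w / w.sum()
    for _ in range(n_events):
        kind = rng.choice(2, p=w)
        seg = model._segment_len(rng, L)
        start = int(rng.integers(0, L))
        if kind == 0:  # inversion
            idxs = [(start + j) % L for j in range(seg)]
            segment = [order[i] for i in idxs]
            segment = [(g, _flip(s)) for g, s in reversed(segment)]
            for i, val in zip(idxs, segment):
                order[i] = val
        else:  # transposition
            if seg >= L:
                continue
            idxs = [(start + j) % L for j in range(seg)]
            segment = [order[i] for i in idxs]
            rest = [order[i] for i in range(L) if i not in set(idxs)]
            insert_at = int(rng.integers(0, len(rest) + 1))
            order = rest[:insert_at] + segment + rest[insert_at:]
    loci = [
        GeneLocus(gene_id=g, replicon_id=rep.replicon_id, index=i, strand=s)
        for i, (g, s) in enumerate(order)
    ]
    replicons[target] = Replicon(rep.replicon_id, loci, circular=rep.circular)
    out_id = genome_id if genome_id is not None else genome.genome_id
    out = GenomeRecord(genome_id=out_id, replicons=replicons,
                       excluded_genes=set(genome.excluded_genes))
    assert out.gene_ids == genome.gene_ids  # content conservation
    return out


def identity_orthomap(a: GenomeRecord, b: GenomeRecord) -> OrthologMap:
    """Identity map on shared gene ids — exact orthology for simulated
    genomes descended from one root."""
    shared = a.gene_ids & b.gene_ids
    return OrthologMap(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        pairs={(g, g) for g in shared},
    )


def evolve_along_tree(
    tree: "PhyloTree",
    root_genome: GenomeRecord,
    model: RearrangementModel,
    seed: int = 0,
) -> tuple[list[GenomeRecord], "PhyloTree"]:
    """Evolve the root genome down a tree; leaves become genomes.

    Each branch receives Poisson(events_rate × branch_length) events.
    Returns the leaf genomes (named by leaf label) and the true tree.
    """
    from .matrices_trees import PhyloTree  # cycle guard

    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    genomes: list[GenomeRecord] = []
    state: dict[int, GenomeRecord] = {id(dtree.seed_node): root_genome}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        parent_genome = state[id(node.parent_node)]
        blen = node.edge.length or 0.0
        n_events = int(rng.poisson(model.events_rate * blen))
        child = apply_events(parent_genome, model, n_events, rng=rng)
        if node.is_leaf():
            child = GenomeRecord(
                genome_id=node.taxon.label,
                replicons=child.replicons,
                excluded_genes=set(child.excluded_genes),
            )
            genomes.append(child)
        state[id(node)] = child
    return genomes, tree


def random_binary_tree(
    n_taxa: int,
    seed: int = 0,
    min_blen: float = 0.1,
    max_blen: float = 1.0,
) -> "PhyloTree":
    """A random unrooted binary tree with uniform random branch lengths —
    the generator for NJ consistency round-trips."""
    from .matrices_trees import PhyloTree

    if n_taxa < 3:
        raise ValueError("need ≥ 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    # sequential random leaf attachment onto a growing unrooted tree
    import dendropy

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def blen() -> float:
        return float(rng.uniform(min_blen, max_blen))

    c0 = dendropy.Node(taxon=taxa.get_taxon(labels[0]))
    c1 = dendropy.Node(taxon=taxa.get_taxon(labels[1]))
    c2 = dendropy.Node(taxon=taxa.get_taxon(labels[2]))
    for c in (c0, c1, c2):
        tree.seed_node.add_child(c)
        c.edge.length = blen()
    edges = [c0.edge, c1.edge, c2.edge]
    for label in labels[3:]:
        edge = edges[int(rng.integers(0, len(edges)))]
        child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(split)
        split.add_child(child)
        half = float(edge.length) * 0.5
        split.edge.length = half
        child.edge.length = half
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        split.add_child(leaf)
        leaf.edge.length = blen()
        edges.extend([split.edge, child.edge, leaf.edge])
    tree.update_bipartitions(suppress_unifurcations=True)
    return PhyloTree(tree)


def additive_matrix(tree: "PhyloTree") -> "DistanceMatrix":
    """Leaf-to-leaf path-length matrix of a tree (exactly additive, so NJ
    must reconstruct the topology)."""
    from .matrices_trees import DistanceMatrix

    dtree = tree.dendropy_tree
    pdm = dtree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in dtree.taxon_namespace)
    n = len(taxa)
    mat = np.zeros((n, n))
    lookup = {t.label: t for t in dtree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(taxa=taxa, values=mat, method="additive")
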