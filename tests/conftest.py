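"""Shared fixtures and independent mini-oracles for the test suite.

The oracles here are deliberately naive re-derivations (tuple rotations,
exhaustive scans) kept independent of the library's vectorized code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import geordi as g


def make_genome(order: list[str], genome_id: str = "G",
                circular: bool = True) -> g.GenomeRecord:
    """Genome with a single replicon holding the given gene order."""
    loci = [
        g.GeneLocus(gene_id=name, replicon_id="chr", index=i)
        for i, name in enumerate(order)
    ]
    return g.GenomeRecord(
        genome_id=genome_id,
        replicons=[g.Replicon("chr", loci, circular=circular)],
    )


def identity_map(a: g.GenomeRecord, b: g.GenomeRecord) -> g.OrthologMap:
    return g.identity_orthomap(a, b)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_order_equal(pos_a, len_a, pos_b, len_b) -> bool:
    """Naive circular-order test: read gene labels around each circle and
    compare B's reading against all rotations and reflections of A's."""
    k = len(pos_a)
    seq_a = tuple(sorted(range(k), key=lambda i: pos_a[i]))
    seq_b = tuple(sorted(range(k), key=lambda i: pos_b[i]))
    variants = set()
    for r in range(k):
        rot = seq_a[r:] + seq_a[:r]
        variants.add(rot)
        variants.add(rot[::-1])
    return seq_b in variants


def brute_raw_distance(a: g.GenomeRecord, b: g.GenomeRecord,
                       k: int, min_gap: int):
    """Exhaustive raw-distance oracle via plain Python (no shared code with
    `exact_raw_distance`).  Genomes must share all gene ids, one replicon."""
    rep_a, rep_b = a.replicons[0], b.replicons[0]
    pos_a = {loc.gene_id: loc.index for loc in rep_a.loci}
    pos_b = {loc.gene_id: loc.index for loc in rep_b.loci}
    genes = sorted(pos_a)
    La, Lb = len(rep_a), len(rep_b)

    def ok_spacing(pos, L):
        for x, y in combinations(pos, 2):
            d = abs(x - y)
            if min(d, L - d) < min_gap:
                return False
        return True

    n_valid = n_fail = 0
    for subset in combinations(genes, k):
        pa = [pos_a[x] for x in subset]
        pb = [pos_b[x] for x in subset]
        if not (ok_spacing(pa, La) and ok_spacing(pb, Lb)):
            continue
        n_valid += 1
        if not brute_order_equal(pa, La, pb, Lb):
            n_fail += 1
    return n_fail, n_valid


def regraft_leaf(tree: g.PhyloTree, leaf_label: str,
                 rng: np.random.Generator) -> g.PhyloTree:
    """Prune one leaf and reattach it on a random other edge."""
    import dendropy

    dt = tree.dendropy_tree.clone(depth=1)
    leaf = next(
        lf for lf in dt.leaf_node_iter() if lf.taxon.label == leaf_label
    )
    parent = leaf.parent_node
    parent.remove_child(leaf)
    dt.suppress_unifurcations()
    edges = [
        nd.edge for nd in dt.preorder_node_iter()
        if nd.parent_node is not None
    ]
    edge = edges[int(rng.integers(0, len(edges)))]
    head, tail = edge.head_node, edge.tail_node
    length = edge.length or 1.0
    split = dendropy.Node()
    tail.remove_child(head)
    tail.add_child(split)
    split.add_child(head)
    split.edge.length = length / 2
    head.edge.length = length / 2
    split.add_child(leaf)
    leaf.edge.length = 1.0
    return g.PhyloTree(dt)


@pytest.fixture
def ring30() -> g.GenomeRecord:
    return g.random_genome(30, "ring30", seed=123)
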