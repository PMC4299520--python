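"""Distance matrices and distance-based tree building.

Assembles symmetric distance matrices from Monte Carlo replicate estimates
(pooled or per-replicate), serializes them to PHYLIP square and NEXUS
distance formats, and provides the tree layer: neighbor joining with
deterministic tie-breaks, midpoint rooting, Robinson–Foulds comparison,
and per-edge support counted over replicate trees.

Replicate support here is not a data bootstrap: the replicates are
independent re-runs of the Monte Carlo sampler, and an edge's support is
the number of replicate trees containing the same bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .order_distance import RawEstimate, correct_estimate


class AssemblyError(ValueError):
    """Raised when replicate estimates do not cover the taxon pairs."""


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric taxa × taxa distance matrix; NaN marks undefined entries
    (a correction outside its domain)."""

    taxa: list[str]
    values: np.ndarray
    method: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            sym = np.isclose(self.values, self.values.T, equal_nan=True)
        if not sym.all():
            raise ValueError("matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    @property
    def has_undefined(self) -> bool:
        iu = np.triu_indices(len(self.taxa), 1)
        return bool(np.isnan(self.values[iu]).any())

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        """Lower-triangle (a, b, d) triples, a < b lexicographically by
        matrix order."""
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                yield self.taxa[i], self.taxa[j], float(self.values[i, j])

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(
            taxa=list(taxa),
            values=self.values[np.ix_(idx, idx)],
            method=self.method,
            provenance=dict(self.provenance),
        )

    # -- serialization ----------------------------------------------------

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{t:<12s} {row}\n")

    @classmethod
    def from_phylip(cls, path: str | Path, method: str = "external") -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split("\n")
        lines = [ln for ln in tokens if ln.strip()]
        n = int(lines[0].split()[0])
        taxa, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
        return cls(taxa=taxa, values=np.array(rows), method=method)

    def to_nexus(self, path: str | Path) -> None:
        """NEXUS DISTANCES block (PAUP-compatible, full matrix)."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={len(self.taxa)};\n")
            fh.write("    TAXLABELS " + " ".join(self.taxa) + ";\nEND;\n\n")
            fh.write("BEGIN DISTANCES;\n")
            fh.write(f"    DIMENSIONS NTAX={len(self.taxa)};\n")
            fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL;\n    MATRIX\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"        {t:<12s} {row}\n")
            fh.write("    ;\nEND;\n")


def assemble_matrix(
    estimates: Sequence[RawEstimate],
    correction: str = "tajima",
    combine: str = "pooled",
    m: int = 60,
) -> "DistanceMatrix | list[DistanceMatrix]":
    """Build distance matrices from per-pair, per-replicate raw estimates.

    ``pooled`` sums k_fail and n across replicates for each pair *before*
    correcting (so 100 replicates of 100,000 iterations correct counts out
    of 10 million); ``per_replicate`` returns one matrix per replicate
    index, the inputs for replicate support counting.
    """
    taxa = sorted({t for e in estimates for t in e.genome_pair})
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    expected = {(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1:]}

    def matrix_from(pair_counts: dict[tuple[str, str], tuple[int, int]],
                    provenance: dict) -> DistanceMatrix:
        missing = expected - set(pair_counts)
        if missing:
            raise AssemblyError(f"missing pairs: {sorted(missing)[:5]}")
        values = np.zeros((n, n))
        for (a, b), (kf, nn) in pair_counts.items():
            est = RawEstimate(genome_pair=(a, b), k_fail=kf, n=nn, seed=0)
            values[index[a], index[b]] = values[index[b], index[a]] = (
                correct_estimate(est, correction, m).value
            )
        return DistanceMatrix(taxa=taxa, values=values, method=correction,
                              provenance=provenance)

    def norm_pair(e: RawEstimate) -> tuple[str, str]:
        return tuple(sorted(e.genome_pair))  # type: ignore[return-value]

    if combine == "pooled":
        counts: dict[tuple[str, str], tuple[int, int]] = {}
        for e in estimates:
            p = norm_pair(e)
            kf, nn = counts.get(p, (0, 0))
            counts[p] = (kf + e.k_fail, nn + e.n)
        prov = {"combine": "pooled",
                "n_per_pair": {f"{a}|{b}": nn for (a, b), (_, nn) in counts.items()}}
        return matrix_from(counts, prov)
    if combine == "per_replicate":
        by_rep: dict[int, dict[tuple[str, str], tuple[int, int]]] = {}
        for e in estimates:
            by_rep.setdefault(e.replicate_index, {})[norm_pair(e)] = (e.k_fail, e.n)
        return [
            matrix_from(by_rep[r], {"combine": "per_replicate", "replicate": r})
            for r in sorted(by_rep)
        ]
    raise ValueError(f"unknown combine mode {combine!r}")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


def _canonical_split(side: frozenset, full: frozenset) -> frozenset:
    """Canonical representative of a bipartition: the side not containing
    the lexicographically smallest taxon."""
    anchor = min(full)
    return full - side if anchor in side else side


class PhyloTree:
    """A phylogenetic tree (dendropy-backed) with optional per-edge
    replicate-support counts keyed by canonical bipartition."""

    def __init__(self, tree: dendropy.Tree,
                 support: Optional[dict[frozenset, int]] = None) -> None:
        self.dendropy_tree = tree
        self.support: dict[frozenset, int] = support or {}

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        obj = cls(tree)
        full = frozenset(obj.taxa)
        # internal node labels, if integers, are replicate-support counts
        for node in tree.preorder_internal_node_iter():
            if node.label is not None:
                try:
                    count = int(node.label)
                except ValueError:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                if 2 <= len(side) <= len(full) - 2:
                    obj.support[_canonical_split(side, full)] = count
        return obj

    def to_newick(self) -> str:
        tree = self.dendropy_tree.clone(depth=1)
        if self.support:
            full = frozenset(self.taxa)
            for node in tree.preorder_internal_node_iter():
                side = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if 2 <= len(side) <= len(full) - 2:
                    key = _canonical_split(side, full)
                    if key in self.support:
                        node.label = str(self.support[key])
        return tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.dendropy_tree.clone(depth=1), dict(self.support))

    # -- basic queries ------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(
            lf.taxon.label for lf in self.dendropy_tree.leaf_node_iter()
        )

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf labels."""
        full = frozenset(self.taxa)
        out = set()
        for node in self.dendropy_tree.preorder_internal_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(full) - 2:
                out.add(_canonical_split(side, full))
        return out

    def restricted_splits(self, taxa: Iterable[str]) -> set[frozenset]:
        """Bipartitions of the tree restricted to a taxon subset.

        The splits of a restricted tree are exactly the intersections of
        the original splits with the subset, dropping trivial ones.
        """
        sub = frozenset(taxa)
        out = set()
        for split in self.splits():
            side = split & sub
            if 2 <= len(side) <= len(sub) - 2:
                out.add(_canonical_split(side, sub))
        return out

    def restrict(self, taxa: Iterable[str]) -> "PhyloTree":
        keep = set(taxa)
        tree = self.dendropy_tree.extract_tree_with_taxa_labels(keep)
        tree.purge_taxon_namespace()
        return PhyloTree(tree)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.dendropy_tree.preorder_edge_iter()
        )


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou–Nei, with the standard Q criterion).

    Deterministic: ties in Q are broken by the lexicographically smallest
    (cluster label, cluster label) pair, where a cluster's label is its
    smallest member taxon.  Negative branch-length estimates are clamped
    to zero with the deficit transferred to the sibling branch.
    """
    if len(matrix) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if matrix.has_undefined:
        raise ValueError(
            "matrix contains undefined entries; impute or prune first"
        )
    taxa = list(matrix.taxa)
    d = matrix.values.astype(float).copy()
    ns = dendropy.TaxonNamespace(sorted(taxa))
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa
    ]
    labels = list(taxa)  # lexicographic tie-break key per cluster
    active = list(range(len(taxa)))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = tuple(sorted((labels[i], labels[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        # new distances
        new_row = {}
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (d[i, kk] + d[j, kk] - d[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for kk, val in new_row.items():
            d[u, kk] = d[kk, u] = val
        active = [x for x in active if x not in (i, j)] + [u]

    # final three-point join
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    center = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the path length are broken by the lexicographically smallest
    (leaf, leaf) endpoint pair.
    """
    work = tree.copy()
    dt = work.dendropy_tree
    leaves = {lf.taxon.label: lf for lf in dt.leaf_node_iter()}
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs ≥ 2 leaves")
    # undirected adjacency with edge lengths
    adj: dict[int, list[tuple[dendropy.Node, float, dendropy.Edge]]] = {}
    node_by_id: dict[int, dendropy.Node] = {}
    for node in dt.preorder_node_iter():
        node_by_id[id(node)] = node
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            adj.setdefault(id(node), []).append((child, length, child.edge))
            adj.setdefault(id(child), []).append((node, length, child.edge))

    def distances_from(start: dendropy.Node):
        dist = {id(start): 0.0}
        prev: dict[int, tuple[int, dendropy.Edge, float]] = {}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nbr, length, edge in adj.get(id(cur), []):
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(cur)] + length
                    prev[id(nbr)] = (id(cur), edge, length)
                    stack.append(nbr)
        return dist, prev

    best = None  # (-length, (u_label, v_label))
    labels = sorted(leaves)
    dist_cache = {}
    for u in labels:
        dist, _ = distances_from(leaves[u])
        dist_cache[u] = dist
        for v in labels:
            if v <= u:
                continue
            cand = (-dist[id(leaves[v])], (u, v))
            if best is None or cand < best:
                best = cand
    path_len = -best[0]  # type: ignore[index]
    if path_len <= 0:
        raise ValueError("all-zero branch lengths: midpoint undefined")
    u_label, v_label = best[1]  # type: ignore[index]
    half = path_len / 2.0
    dist, prev = distances_from(leaves[u_label])
    # walk back from v toward u to find the midpoint edge
    cur = id(leaves[v_label])
    while cur in prev:
        parent_id, edge, length = prev[cur]
        if dist[parent_id] <= half <= dist[cur] + 1e-12:
            offset = half - dist[parent_id]  # from the u-side node
            if math.isclose(offset, 0.0, abs_tol=1e-12):
                dt.reroot_at_node(node_by_id[parent_id],
                                  update_bipartitions=False)
            elif math.isclose(offset, length, abs_tol=1e-12):
                dt.reroot_at_node(node_by_id[cur], update_bipartitions=False)
            else:
                # edge runs child(head) -> parent(tail) in dendropy terms
                head = edge.head_node
                toward_u_is_tail = id(edge.tail_node) == parent_id
                from_head = (length - offset) if toward_u_is_tail else offset
                dt.reroot_at_edge(
                    edge,
                    length1=length - from_head,
                    length2=from_head,
                    update_bipartitions=False,
                )
            dt.is_rooted = True
            return PhyloTree(dt, dict(tree.support))
        cur = parent_id
    raise RuntimeError("midpoint edge not found")  # pragma: no cover


# ---------------------------------------------------------------------------
# Robinson–Foulds and replicate support
# ---------------------------------------------------------------------------


def rf_distance(t1: PhyloTree, t2: PhyloTree, restrict: str = "shared_taxa") -> int:
    """Symmetric-difference (Robinson–Foulds) count of non-trivial
    bipartitions, after restricting both trees to their shared leaf set."""
    s1, s2 = set(t1.taxa), set(t2.taxa)
    if restrict == "strict":
        if s1 != s2:
            raise ValueError("strict mode requires identical taxon sets")
        shared = s1
    elif restrict == "shared_taxa":
        shared = s1 & s2
    else:
        raise ValueError(f"unknown restrict mode {restrict!r}")
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared taxa: RF undefined")
    a = t1.restricted_splits(shared)
    b = t2.restricted_splits(shared)
    return len(a ^ b)


def support_from_replicates(
    reference: PhyloTree, replicate_trees: Sequence[PhyloTree]
) -> PhyloTree:
    """Annotate each internal edge of the reference with the number of
    replicate trees containing the same bipartition (restricted to the
    reference's taxon set)."""
    ref_taxa = set(reference.taxa)
    counts: dict[frozenset, int] = {s: 0 for s in reference.splits()}
    for rep in replicate_trees:
        rep_splits = rep.restricted_splits(ref_taxa)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    out = reference.copy()
    out.support = counts
    return out


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def read_newick_list(path: str | Path) -> list[PhyloTree]:
    """Read a multi-tree Newick file (one tree per line/semicolon)."""
    text = Path(path).read_text()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(PhyloTree.from_newick(chunk.strip() + ";"))
    return trees
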