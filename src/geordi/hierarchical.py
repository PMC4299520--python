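"""Hierarchical, ranked-pair tree building.

Short gene-order distances are estimated with far more confidence than
long (near-saturated) ones, so trees are grown from a list of taxon pairs
ranked by ascending distance: pairs are admitted one at a time; whenever
the admitted pairs complete a clique of ≥4 taxa, an NJ tree is built on
that clique and retained only if congruent (restricted RF 0) with every
previously retained tree.  Retained trees that are fully contained in a
newer congruent tree are absorbed, and compatible trees are merged by
rebuilding NJ on the union taxon set — the union is kept only when its
restrictions reproduce both original topologies.  A second phase adds
remaining taxa one at a time to the largest tree, accepting an addition
only when it leaves the prior topology intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .matrices_trees import DistanceMatrix, PhyloTree, nj_tree, rf_distance


@dataclass(frozen=True)
class RankedPair:
    rank: int  # 1-based
    pair: tuple[str, str]
    distance: float


@dataclass
class RankedPairList:
    pairs: list[RankedPair]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class LedgerEntry:
    formation_rank: int
    last_pair_rank: int
    taxon_set: frozenset
    tree: PhyloTree


@dataclass
class TreeLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    @property
    def largest(self) -> Optional[LedgerEntry]:
        if not self.entries:
            return None
        return max(
            self.entries,
            key=lambda e: (len(e.taxon_set), -e.formation_rank,
                           tuple(sorted(e.taxon_set))),
        )

    def to_rows(self) -> list[tuple[int, int, str, str]]:
        """(formation_rank, last_rank, taxa, newick) rows for the TSV."""
        return [
            (e.formation_rank, e.last_pair_rank,
             ",".join(sorted(e.taxon_set)), e.tree.to_newick())
            for e in self.entries
        ]


def build_ranked_list(matrix: DistanceMatrix) -> RankedPairList:
    """Rank all unordered taxon pairs by ascending distance.

    Equal distances fall back to lexicographic pair order; undefined
    entries are ranked last (they carry the least information).
    """
    import math

    rows = []
    for a, b, d in matrix.pairs():
        key_pair = tuple(sorted((a, b)))
        undefined = math.isnan(d)
        rows.append((undefined, math.inf if undefined else d, key_pair, d))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return RankedPairList(
        pairs=[
            RankedPair(rank=i + 1, pair=key, distance=d)
            for i, (_, _, key, d) in enumerate(rows)
        ]
    )


def _congruent(t1: PhyloTree, t2: PhyloTree) -> bool:
    """Restricted RF 0 on shared taxa; < 4 shared is vacuously congruent."""
    shared = set(t1.taxa) & set(t2.taxa)
    if len(shared) < 4:
        return True
    return rf_distance(t1, t2) == 0


def _try_combine(
    t1: LedgerEntry, t2: LedgerEntry, matrix: DistanceMatrix, rank: int
) -> Optional[LedgerEntry]:
    """NJ on the union taxon set; keep only if both backbones survive."""
    union = sorted(t1.taxon_set | t2.taxon_set)
    tree = nj_tree(matrix.submatrix(union))
    for old in (t1, t2):
        if len(old.taxon_set) >= 4:
            if rf_distance(tree.restrict(sorted(old.taxon_set)), old.tree) != 0:
                return None
    return LedgerEntry(
        formation_rank=min(t1.formation_rank, t2.formation_rank),
        last_pair_rank=rank,
        taxon_set=frozenset(union),
        tree=tree,
    )


def grow_trees(ranked: RankedPairList, matrix: DistanceMatrix) -> TreeLedger:
    """Walk the ranked pair list, admitting trees clique by clique.

    A taxon set becomes buildable when the admitted pairs form a clique of
    ≥ 4 members (NJ needs a complete submatrix); only cliques containing
    the newly admitted pair are considered at each rank.  New trees
    incongruent with any retained tree are rejected; congruent ones absorb
    retained trees they contain, then merge with compatible neighbours.
    """
    graph = nx.Graph()
    ledger = TreeLedger()
    for rp in ranked:
        a, b = rp.pair
        graph.add_edge(a, b)
        neighbors = set(graph.neighbors(a)) & set(graph.neighbors(b))
        if len(neighbors) < 2:
            continue
        sub = graph.subgraph(neighbors | {a, b})
        cliques = [
            frozenset(c) for c in nx.find_cliques(sub)
            if a in c and b in c and len(c) >= 4
        ]
        for clique in sorted(cliques, key=lambda c: tuple(sorted(c))):
            if any(clique <= e.taxon_set for e in ledger.entries):
                continue  # already represented
            taxa = sorted(clique)
            tree = nj_tree(matrix.submatrix(taxa))
            if not all(_congruent(tree, e.tree) for e in ledger.entries):
                continue
            entry = LedgerEntry(
                formation_rank=rp.rank,
                last_pair_rank=rp.rank,
                taxon_set=clique,
                tree=tree,
            )
            # absorb retained trees fully contained in the new tree
            ledger.entries = [
                e for e in ledger.entries if not e.taxon_set <= clique
            ]
            ledger.entries.append(entry)
            # one combination pass per admission, in ledger order
            merged = True
            while merged:
                merged = False
                for i in range(len(ledger.entries)):
                    for j in range(i + 1, len(ledger.entries)):
                        e1, e2 = ledger.entries[i], ledger.entries[j]
                        if not _congruent(e1.tree, e2.tree):
                            continue
                        combo = _try_combine(e1, e2, matrix, rp.rank)
                        if combo is not None:
                            ledger.entries = [
                                e for k, e in enumerate(ledger.entries)
                                if k not in (i, j)
                            ]
                            ledger.entries.append(combo)
                            merged = True
                            break
                    if merged:
                        break
    return ledger


def add_single_taxa(
    ledger_tree: PhyloTree,
    matrix: DistanceMatrix,
    ranked: RankedPairList,
) -> PhyloTree:
    """Second phase: single-taxon addition to the largest retained tree.

    Candidates are visited in order of their smallest ranked distance to
    any current tree member; a candidate is accepted iff the NJ tree on
    the union, restricted to the prior taxa, reproduces the prior
    topology.  Repeats until a full pass accepts nobody.
    """
    current = ledger_tree
    members = set(current.taxa)
    all_taxa = set(matrix.taxa)
    changed = True
    while changed:
        changed = False
        outside = all_taxa - members
        best_rank: dict[str, int] = {}
        for rp in ranked:
            a, b = rp.pair
            for cand, anchor in ((a, b), (b, a)):
                if cand in outside and anchor in members:
                    best_rank.setdefault(cand, rp.rank)
        candidates = sorted(best_rank, key=lambda c: (best_rank[c], c))
        for cand in candidates:
            taxa = sorted(members | {cand})
            tree = nj_tree(matrix.submatrix(taxa))
            if rf_distance(tree.restrict(sorted(members)), current) == 0:
                current = tree
                members.add(cand)
                changed = True
                break
    return current
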