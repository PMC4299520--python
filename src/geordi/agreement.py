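"""Agreement subtrees over a collection of trees.

An agreement set is a taxon subset on which every tree in the collection,
after pruning to that subset, has the identical unrooted topology.  The
maximum agreement subtree problem for more than two trees is NP-hard, so
two routes are provided: exhaustive search over taxon subsets (largest
first) that returns *all* maximum-cardinality agreement sets on small
instances, and a greedy conflict-pruning heuristic for larger ones that
returns one (not necessarily maximum) agreement set.

Topology identity is tested on restricted bipartition sets: the splits of
a pruned tree are the non-trivial intersections of the original splits
with the subset, so no explicit pruning is needed.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

from .matrices_trees import PhyloTree, _canonical_split


def _split_sets(trees: Sequence[PhyloTree]) -> tuple[list[set[frozenset]], list[str]]:
    taxa_sets = [set(t.taxa) for t in trees]
    common = set.intersection(*taxa_sets)
    return [t.restricted_splits(common) for t in trees], sorted(common)


def _restricted(splits: set[frozenset], subset: frozenset) -> frozenset:
    out = set()
    for s in splits:
        side = s & subset
        if 2 <= len(side) <= len(subset) - 2:
            out.add(_canonical_split(side, subset))
    return frozenset(out)


def _all_agree(split_sets: Sequence[set[frozenset]], subset: frozenset) -> bool:
    first = _restricted(split_sets[0], subset)
    return all(_restricted(s, subset) == first for s in split_sets[1:])


def agreement_subtree_exact(
    trees: Sequence[PhyloTree], max_taxa: int = 20
) -> list[tuple[frozenset, PhyloTree]]:
    """All maximum-cardinality agreement sets, by exhaustive search.

    Scans subset sizes from the full common taxon set downward and stops
    at the first size with at least one agreement set; every 3-taxon
    subset agrees trivially, so the search always terminates.  Refuses
    instances with more than ``max_taxa`` common taxa.
    """
    if len(trees) < 1:
        raise ValueError("need at least one tree")
    split_sets, common = _split_sets(trees)
    if len(common) > max_taxa:
        raise ValueError(
            f"{len(common)} common taxa exceeds exact-search limit "
            f"{max_taxa}; use the heuristic"
        )
    for size in range(len(common), 2, -1):
        hits = []
        for subset in combinations(common, size):
            fs = frozenset(subset)
            if _all_agree(split_sets, fs):
                hits.append(fs)
        if hits:
            return [
                (fs, trees[0].restrict(sorted(fs))) for fs in sorted(
                    hits, key=lambda s: tuple(sorted(s))
                )
            ]
    return []  # pragma: no cover — size 3 always agrees


def agreement_subtree_heuristic(
    trees: Sequence[PhyloTree],
) -> tuple[frozenset, PhyloTree]:
    """Greedy conflict pruning: repeatedly remove the taxon whose removal
    most reduces the total pairwise split disagreement, until all trees
    agree on the remaining set.

    Ties on the reduction are broken by the lexicographically smallest
    taxon label.  Terminates because any 3-taxon set agrees.  The result
    is an agreement set but not necessarily a maximum one.
    """
    if len(trees) < 2:
        raise ValueError("need ≥ 2 trees")
    split_sets, common = _split_sets(trees)
    if len(common) < 4:
        raise ValueError("need ≥ 4 shared taxa")
    current = frozenset(common)

    def total_conflict(subset: frozenset) -> int:
        restricted = [_restricted(s, subset) for s in split_sets]
        return sum(
            len(a ^ b)
            for i, a in enumerate(restricted)
            for b in restricted[i + 1:]
        )

    conflict = total_conflict(current)
    while conflict > 0 and len(current) > 3:
        best = None  # (remaining_conflict, taxon)
        for taxon in sorted(current):
            cand = total_conflict(current - {taxon})
            if best is None or (cand, taxon) < best:
                best = (cand, taxon)
        conflict, removed = best  # type: ignore[misc]
        current = current - {removed}
    return current, trees[0].restrict(sorted(current))
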