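"""Ortholog gene-content distance and matrix correlation.

Gene-content similarity S is the number of ortholog pairs shared by two
genomes divided by the gene count of the smaller genome (after exclusion
masks, genome-wide — content is not restricted to one replicon even when
the order distance is).  Distance is −ln(S), or 1−S in the alternative
mode; the two give similar correlation behaviour.

`correlate_matrices` regresses one distance matrix on another over their
shared taxon pairs — the comparison used to relate gene-order divergence
to rRNA or gene-content divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .genome_model import GenomeRecord, OrthologMap
from .matrices_trees import DistanceMatrix


@dataclass(frozen=True)
class ContentDistance:
    S: float
    value: float
    mode: str

    @property
    def defined(self) -> bool:
        return not math.isinf(self.value)


def gene_content_distance(
    a: GenomeRecord,
    b: GenomeRecord,
    orthomap: OrthologMap,
    mode: str = "neglog",
) -> ContentDistance:
    """S = shared orthologs / smaller genome size; distance −ln S or 1−S.

    Ortholog pairs touching an excluded gene are not counted, matching the
    masked gene counts in the denominator.  Zero shared orthologs signal
    an infinite distance.
    """
    if mode not in ("neglog", "one_minus"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = {
        (ga, gb)
        for ga, gb in orthomap.pairs
        if ga not in a.excluded_genes and gb not in b.excluded_genes
    }
    smaller = min(a.n_genes, b.n_genes)
    if smaller < 1:
        raise ValueError("genome has no genes after exclusions")
    S = len(pairs) / smaller
    if S == 0:
        return ContentDistance(S=0.0, value=math.inf, mode=mode)
    value = -math.log(S) if mode == "neglog" else 1.0 - S
    return ContentDistance(S=S, value=value, mode=mode)


def correlate_matrices(
    x: DistanceMatrix,
    y: DistanceMatrix,
    x_threshold: Optional[float] = None,
) -> tuple[float, float, float, int]:
    """OLS of y on x over shared lower-triangle taxon pairs.

    Pairs with an undefined entry in either matrix are dropped; if
    ``x_threshold`` is given only pairs with x < threshold enter (the
    short-distance regime where divergence measures correlate best).
    Returns (r_squared, slope, intercept, n_pairs).
    """
    shared = sorted(set(x.taxa) & set(y.taxa))
    if len(shared) < 3:
        raise ValueError("need ≥ 3 shared taxa")
    xs, ys = [], []
    for i, a in enumerate(shared):
        for b in shared[i + 1:]:
            xv, yv = x.get(a, b), y.get(a, b)
            if math.isnan(xv) or math.isnan(yv):
                continue
            if x_threshold is not None and xv >= x_threshold:
                continue
            xs.append(xv)
            ys.append(yv)
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable pairs")
    res = stats.linregress(np.array(xs), np.array(ys))
    return float(res.rvalue**2), float(res.slope), float(res.intercept), len(xs)
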