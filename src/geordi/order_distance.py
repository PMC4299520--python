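"""Distributed gene order distance.

The statistic: repeatedly draw k (five or six) shared orthologs from a pair
of genomes, requiring every chosen gene to be at least ``min_gap`` positions
away from every other along the chromosome in *both* genomes (to avoid
sampling within one operon), and test whether the k orthologs appear in the
same order around both circular chromosomes, ignoring gene orientation.
The raw distance D is the fraction of draws that fail the order test.

Because k labels admit only m = (k-1)!/2 distinct circular arrangements up
to rotation and reflection (60 for k=6, 12 for k=5), D saturates at
(m-1)/m as gene order randomizes — 59/60 ≈ 0.983 for six genes.  Three
corrections map D to an additive divergence:

* ``jc``     — adapted Jukes-Cantor, −((m−1)/m)·ln(1 − (m/(m−1))·D);
  undefined once D ≥ (m−1)/m.
* ``tajima`` — Tajima's falling-factorial series on the raw counts (k, n),
  finite for every k ≤ n; the moment-series analogue of ``jc``.
* ``logcorr`` — the simple D′ = −ln(1−D).

An exhaustive enumeration oracle (`exact_raw_distance`) computes the exact
expectation the sampler estimates, for small genomes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterator, Optional, Sequence, TextIO

import numpy as np

from .genome_model import GenomeRecord, OrthologMap, restrict_to_replicon


class EstimationError(ValueError):
    """Raised when a genome pair cannot support the estimator."""


class UnsatisfiableSpacingError(EstimationError):
    """Raised when nearly no draw can satisfy the spacing requirement."""


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------


def _parse_m_constant(m_constant: str | int, k_genes: int) -> int:
    if m_constant == "auto":
        return math.factorial(k_genes - 1) // 2
    if isinstance(m_constant, str) and m_constant.startswith("fixed:"):
        return int(m_constant.split(":", 1)[1])
    return int(m_constant)


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the Monte Carlo sampler.

    ``n_iter`` counts *valid* draws per replicate (draws rejected for
    spacing are redrawn and not counted).  ``m_constant`` is the circular
    arrangement count used by the corrections; ``auto`` gives (k−1)!/2
    (60 for k=6, 12 for k=5) while ``fixed:60`` applies the six-gene
    constant to five-gene runs.
    """

    k_genes: int = 6
    min_gap: int = 5
    n_iter: int = 100_000
    n_replicates: int = 100
    seed: int = 0
    replicon_mode: str = "largest"  # or "per-replicon"
    m_constant: str | int = "auto"

    def __post_init__(self) -> None:
        if self.k_genes not in (5, 6):
            raise ValueError("k_genes must be 5 or 6")
        if self.min_gap < 1 or self.n_iter < 1 or self.n_replicates < 1:
            raise ValueError("min_gap, n_iter, n_replicates must be ≥ 1")
        if self.replicon_mode not in ("largest", "per-replicon"):
            raise ValueError(f"unknown replicon_mode {self.replicon_mode!r}")

    @property
    def m(self) -> int:
        return _parse_m_constant(self.m_constant, self.k_genes)


@dataclass(frozen=True)
class RawEstimate:
    """Monte Carlo outcome for one genome pair and one replicate."""

    genome_pair: tuple[str, str]
    k_fail: int
    n: int
    seed: int
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.k_fail <= self.n:
            raise ValueError("need 0 ≤ k_fail ≤ n")

    @property
    def D(self) -> float:
        return self.k_fail / self.n

    @property
    def std_error(self) -> float:
        d = self.D
        return math.sqrt(d * (1.0 - d) / self.n)


@dataclass(frozen=True)
class CorrectedDistance:
    """A raw or corrected distance value; ``value`` is NaN when undefined."""

    method: str  # raw | jc | tajima | logcorr
    value: float
    m: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


# ---------------------------------------------------------------------------
# Order test and spacing rule
# ---------------------------------------------------------------------------


def _order_ok_batch(
    pa: np.ndarray, pb: np.ndarray, allow_rotation: bool = True
) -> np.ndarray:
    """Vectorized circular-order test on (B, k) position arrays.

    Reads the k orthologs around genome A to assign each a rank, reads them
    around genome B, and accepts iff the rank sequence around B is the
    identity up to rotation (if either replicon is circular) and reflection
    (always: orientation is not meaningful).
    """
    k = pa.shape[1]
    rank_a = np.argsort(np.argsort(pa, axis=1), axis=1)
    order_b = np.argsort(pb, axis=1)
    seq = np.take_along_axis(rank_a, order_b, axis=1)
    if allow_rotation:
        diffs = (np.roll(seq, -1, axis=1) - seq) % k
        fwd = np.all(diffs == 1, axis=1)
        rev = np.all(diffs == k - 1, axis=1)
    else:
        ident = np.arange(k)
        fwd = np.all(seq == ident, axis=1)
        rev = np.all(seq == ident[::-1], axis=1)
    return fwd | rev


def circular_order_equal(
    positions_a: Sequence[int],
    len_a: int,
    positions_b: Sequence[int],
    len_b: int,
    circular_a: bool = True,
    circular_b: bool = True,
) -> bool:
    """Are the k paired orthologs in the same order around both genomes?

    ``positions_a[i]`` and ``positions_b[i]`` index the same ortholog on
    circles (or linear contigs) of lengths ``len_a`` and ``len_b``.  Order
    is compared up to rotation and reflection of the circle; for linear
    replicons only reflection applies.
    """
    pa = np.asarray(positions_a, dtype=np.int64)
    pb = np.asarray(positions_b, dtype=np.int64)
    if pa.shape != pb.shape or pa.ndim != 1:
        raise ValueError("position sequences must be 1-D and equal length")
    if len(set(pa.tolist())) != pa.size or len(set(pb.tolist())) != pb.size:
        raise ValueError("positions must be distinct within each genome")
    if pa.size and (pa.max() >= len_a or pb.max() >= len_b):
        raise ValueError("position exceeds replicon length")
    return bool(
        _order_ok_batch(pa[None, :], pb[None, :], circular_a or circular_b)[0]
    )


def _spacing_ok_batch(
    pos: np.ndarray, L: int, min_gap: int, circular: bool = True
) -> np.ndarray:
    """Vectorized spacing rule on a (B, k) position array for one genome."""
    d = np.abs(pos[:, :, None] - pos[:, None, :])
    if circular:
        d = np.minimum(d, L - d)
    k = pos.shape[1]
    iu = np.triu_indices(k, 1)
    return np.all(d[:, iu[0], iu[1]] >= min_gap, axis=1)


def spacing_valid(
    positions: Sequence[int], L: int, min_gap: int, circular: bool = True
) -> bool:
    """True iff every pair of positions is ≥ min_gap apart on the circle.

    Separation is the circular index distance min(|i−j|, L−|i−j|); for a
    linear contig it is |i−j|.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(set(pos.tolist())) != pos.size:
        raise ValueError("positions must be distinct")
    return bool(_spacing_ok_batch(pos[None, :], L, min_gap, circular)[0])


# ---------------------------------------------------------------------------
# Shared-ortholog extraction
# ---------------------------------------------------------------------------


@dataclass
class _OrthologGroup:
    """Shared orthologs co-resident on one replicon pair."""

    pos_a: np.ndarray
    pos_b: np.ndarray
    len_a: int
    len_b: int
    circular_a: bool
    circular_b: bool
    gene_pairs: list[tuple[str, str]]


def _shared_ortholog_groups(
    a: GenomeRecord,
    b: GenomeRecord,
    orthomap: OrthologMap,
    cfg: SamplerConfig,
) -> list[_OrthologGroup]:
    if cfg.replicon_mode == "largest":
        a = restrict_to_replicon(a, "largest")
        b = restrict_to_replicon(b, "largest")
    idx_a, idx_b = a.position_index(), b.position_index()
    rep_a = {r.replicon_id: r for r in a.replicons}
    rep_b = {r.replicon_id: r for r in b.replicons}
    grouped: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ga, gb in sorted(orthomap.pairs):
        if ga in a.excluded_genes or gb in b.excluded_genes:
            continue
        la, lb = idx_a.get(ga), idx_b.get(gb)
        if la is None or lb is None:
            continue
        grouped.setdefault((la[0], lb[0]), []).append((la[1], lb[1], ga, gb))
    groups = []
    for (ra, rb), rows in sorted(grouped.items()):
        if len(rows) < cfg.k_genes:
            continue
        groups.append(
            _OrthologGroup(
                pos_a=np.array([r[0] for r in rows], dtype=np.int64),
                pos_b=np.array([r[1] for r in rows], dtype=np.int64),
                len_a=len(rep_a[ra]),
                len_b=len(rep_b[rb]),
                circular_a=rep_a[ra].circular,
                circular_b=rep_b[rb].circular,
                gene_pairs=[(r[2], r[3]) for r in rows],
            )
        )
    return groups


def _pair_stream_seed(
    seed: int, genome_a: str, genome_b: str, replicate: int
) -> np.random.SeedSequence:
    """Independent, order-independent RNG stream per (pair, replicate)."""
    ha = zlib.crc32(genome_a.encode()) & 0x7FFFFFFF
    hb = zlib.crc32(genome_b.encode()) & 0x7FFFFFFF
    lo, hi = sorted((ha, hb))
    return np.random.SeedSequence([seed & 0x7FFFFFFF, lo, hi, replicate])


# ---------------------------------------------------------------------------
# The Monte Carlo sampler
# ---------------------------------------------------------------------------

_BATCH = 16_384
_PROBE_ATTEMPTS = 10_000
_PROBE_MIN_ACCEPT = 1e-3


def sample_raw_distance(
    a: GenomeRecord,
    b: GenomeRecord,
    orthomap: OrthologMap,
    cfg: SamplerConfig,
    replicate_index: int = 0,
    audit_log: Optional[TextIO] = None,
) -> RawEstimate:
    """Estimate the raw distributed gene order distance for one replicate.

    Performs ``cfg.n_iter`` valid draws of ``cfg.k_genes`` ortholog pairs
    chosen uniformly without replacement; draws violating the spacing rule
    in either genome are discarded and redrawn without counting.  The
    result is deterministic given (seed, genome pair, replicate index).

    If ``audit_log`` is given, one tab-separated line per valid draw is
    written: gene ids (a:b, comma-joined), positions in a, positions in b,
    and pass/fail — a hook for composition audits of the sampled sets.
    """
    groups = _shared_ortholog_groups(a, b, orthomap, cfg)
    if not groups:
        raise EstimationError(
            f"{a.genome_id}/{b.genome_id}: fewer than {cfg.k_genes} shared "
            "orthologs co-resident on any replicon pair"
        )
    rng = np.random.default_rng(
        _pair_stream_seed(cfg.seed, a.genome_id, b.genome_id, replicate_index)
    )
    weights = np.array([g.pos_a.size for g in groups], dtype=float)
    weights /= weights.sum()
    k = cfg.k_genes

    n_valid = 0
    n_fail = 0
    attempts = 0
    probe_valid = 0
    probe_done = False
    while n_valid < cfg.n_iter:
        # assign each attempted draw in the batch to a replicon-pair group;
        # validity and truncation are applied in attempt order so that no
        # group is over-represented when n_iter is reached mid-batch
        if len(groups) == 1:
            group_of = np.zeros(_BATCH, dtype=np.int64)
        else:
            group_of = rng.choice(len(groups), size=_BATCH, p=weights)
        idx_all = np.zeros((_BATCH, k), dtype=np.int64)
        valid = np.zeros(_BATCH, dtype=bool)
        same = np.zeros(_BATCH, dtype=bool)
        for gi, g in enumerate(groups):
            sel = np.nonzero(group_of == gi)[0]
            if sel.size == 0:
                continue
            idx = rng.integers(0, g.pos_a.size, size=(sel.size, k))
            idx_all[sel] = idx
            srt = np.sort(idx, axis=1)
            distinct = (srt[:, 1:] != srt[:, :-1]).all(axis=1)
            pa, pb = g.pos_a[idx], g.pos_b[idx]
            ok = distinct & _spacing_ok_batch(
                pa, g.len_a, cfg.min_gap, g.circular_a
            ) & _spacing_ok_batch(pb, g.len_b, cfg.min_gap, g.circular_b)
            valid[sel] = ok
            attempts += int(distinct.sum())
            if ok.any():
                same[sel[ok]] = _order_ok_batch(
                    pa[ok], pb[ok], g.circular_a or g.circular_b
                )
        if not probe_done:
            probe_valid += int(valid.sum())
        taken = np.nonzero(valid)[0][: cfg.n_iter - n_valid]
        n_valid += taken.size
        n_fail += int(taken.size - same[taken].sum())
        if audit_log is not None:
            for pos in taken:
                g = groups[group_of[pos]]
                row = idx_all[pos]
                genes = ",".join(
                    f"{g.gene_pairs[i][0]}:{g.gene_pairs[i][1]}" for i in row
                )
                pos_a = ",".join(str(g.pos_a[i]) for i in row)
                pos_b = ",".join(str(g.pos_b[i]) for i in row)
                verdict = "pass" if same[pos] else "fail"
                audit_log.write(f"{genes}\t{pos_a}\t{pos_b}\t{verdict}\n")
        if not probe_done and attempts >= _PROBE_ATTEMPTS:
            probe_done = True
            if probe_valid / attempts < _PROBE_MIN_ACCEPT:
                raise UnsatisfiableSpacingError(
                    f"{a.genome_id}/{b.genome_id}: spacing rule rejected "
                    f"{attempts - probe_valid}/{attempts} probe draws"
                )
    return RawEstimate(
        genome_pair=(a.genome_id, b.genome_id),
        k_fail=n_fail,
        n=n_valid,
        seed=cfg.seed,
        replicate_index=replicate_index,
    )


def sample_replicates(
    a: GenomeRecord,
    b: GenomeRecord,
    orthomap: OrthologMap,
    cfg: SamplerConfig,
) -> list[RawEstimate]:
    """All ``cfg.n_replicates`` independent replicate estimates for a pair."""
    return [
        sample_raw_distance(a, b, orthomap, cfg, replicate_index=r)
        for r in range(cfg.n_replicates)
    ]


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

_ORACLE_BUDGET = 10_000_000


def exact_raw_distance(
    a: GenomeRecord,
    b: GenomeRecord,
    orthomap: OrthologMap,
    cfg: SamplerConfig,
) -> Fraction:
    """Exact expectation of the sampler: enumerate every spacing-valid
    k-subset of shared orthologs and return the exact failing fraction.

    Only for small instances (single replicon pair, ≤ 10^7 subsets); the
    Monte Carlo sampler converges to this value as n → ∞.
    """
    groups = _shared_ortholog_groups(a, b, orthomap, cfg)
    if len(groups) != 1:
        raise EstimationError("exact oracle requires a single replicon pair")
    g = groups[0]
    n_orth = g.pos_a.size
    if math.comb(n_orth, cfg.k_genes) > _ORACLE_BUDGET:
        raise EstimationError("combinatorial budget exceeded; oracle is for tests")
    n_valid = 0
    n_fail = 0
    for chunk in _combination_chunks(n_orth, cfg.k_genes, 100_000):
        pa, pb = g.pos_a[chunk], g.pos_b[chunk]
        ok = _spacing_ok_batch(
            pa, g.len_a, cfg.min_gap, g.circular_a
        ) & _spacing_ok_batch(pb, g.len_b, cfg.min_gap, g.circular_b)
        pa, pb = pa[ok], pb[ok]
        n_valid += pa.shape[0]
        same = _order_ok_batch(pa, pb, g.circular_a or g.circular_b)
        n_fail += int(pa.shape[0] - same.sum())
    if n_valid == 0:
        raise UnsatisfiableSpacingError("no spacing-valid subset exists")
    return Fraction(n_fail, n_valid)


def _combination_chunks(n: int, k: int, chunk: int) -> Iterator[np.ndarray]:
    buf: list[tuple[int, ...]] = []
    for comb in combinations(range(n), k):
        buf.append(comb)
        if len(buf) == chunk:
            yield np.array(buf, dtype=np.int64)
            buf = []
    if buf:
        yield np.array(buf, dtype=np.int64)


# ---------------------------------------------------------------------------
# Divergence corrections
# ---------------------------------------------------------------------------


def jc_correction(D: float, m: int) -> CorrectedDistance:
    """Adapted Jukes-Cantor correction −((m−1)/m)·ln(1 − (m/(m−1))·D).

    ``m`` is the number of circular arrangement classes (60 for six genes).
    Undefined (NaN value) once D ≥ (m−1)/m, the random-order expectation.
    """
    if D < 0:
        raise ValueError("D must be ≥ 0")
    c = (m - 1) / m
    if D >= c:
        return CorrectedDistance(method="jc", value=math.nan, m=m)
    return CorrectedDistance(method="jc", value=-c * math.log1p(-D / c), m=m)


def tajima_correction(k_fail: int, n: int, m: int) -> CorrectedDistance:
    """Tajima's falling-factorial series estimator of the corrected distance.

    Sum over i = 1..k_fail of k^(i) / (i · ((m−1)/m)^(i−1) · n^(i)) with
    k^(i) = k!/(k−i)! — finite for every k_fail ≤ n, which is the point:
    it keeps saturated pairs (D ≥ (m−1)/m) in the analysis.  Terms are
    generated by an exact recurrence and truncated once the relative term
    drops below 1e−12.
    """
    if not 0 <= k_fail <= n:
        raise ValueError("need 0 ≤ k_fail ≤ n")
    if k_fail == 0:
        return CorrectedDistance(method="tajima", value=0.0, m=m)
    ratio_m = m / (m - 1)
    total = 0.0
    term = k_fail / n  # i = 1
    i = 1
    while True:
        total += term
        if i >= k_fail:
            break
        if term < 1e-12 * total:
            break
        term *= ((k_fail - i) / (n - i)) * (i / (i + 1)) * ratio_m
        i += 1
    return CorrectedDistance(method="tajima", value=total, m=m)


def log_correction(D: float) -> CorrectedDistance:
    """The simple saturation correction D′ = −ln(1 − D)."""
    if D < 0:
        raise ValueError("D must be ≥ 0")
    if D >= 1:
        return CorrectedDistance(method="logcorr", value=math.nan, m=0)
    return CorrectedDistance(method="logcorr", value=-math.log1p(-D), m=0)


def correct_estimate(est: RawEstimate, method: str, m: int) -> CorrectedDistance:
    """Apply a named correction to a raw estimate.

    ``raw`` passes D through; ``jc`` and ``logcorr`` act on D = k/n;
    ``tajima`` acts on the integer counts themselves.
    """
    if method == "raw":
        return CorrectedDistance(method="raw", value=est.D, m=m)
    if method == "jc":
        return jc_correction(est.D, m)
    if method == "tajima":
        return tajima_correction(est.k_fail, est.n, m)
    if method in ("logcorr", "log"):
        return log_correction(est.D)
    raise ValueError(f"unknown correction method {method!r}")
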