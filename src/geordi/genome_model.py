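"""Domain model for gene orders and orthology.

A genome is one or more replicons (chromosomes/plasmids), each an ordered
list of gene loci.  Gene positions are 0-based consecutive ranks along the
replicon, not nucleotide coordinates: the distributed gene order distance is
a purely ordinal statistic, so nucleotide spacing never matters.  Strand is
recorded for completeness but the order test ignores orientation.

Orthology between two genomes is a one-to-one gene-id mapping, either read
from a two-column table or inferred from all-vs-all similarity hits by the
reciprocal-best-hit (RBH) rule: a pair (a, b) is accepted only when b is the
unique top-scoring subject of query a and vice versa.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


Strand = Literal["+", "-", "?"]


@dataclass(frozen=True)
class GeneLocus:
    """One gene at an ordinal position on a replicon.

    ``index`` is the 0-based rank along the replicon.  ``strand`` is one of
    ``+``, ``-`` or ``?`` (unknown) and is never consulted by the order test.
    """

    gene_id: str
    replicon_id: str
    index: int
    strand: Strand = "?"


@dataclass
class Replicon:
    """An ordered, by default circular, sequence of gene loci."""

    replicon_id: str
    loci: list[GeneLocus]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.loci:
            raise FormatError(f"replicon {self.replicon_id!r} has no genes")
        self.loci = sorted(self.loci, key=lambda g: g.index)
        indices = [g.index for g in self.loci]
        if indices != list(range(len(indices))):
            raise FormatError(
                f"replicon {self.replicon_id!r}: indices must be consecutive "
                f"0..L-1, got {indices[:10]}..."
            )

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.loci]


@dataclass
class GenomeRecord:
    """A genome: one or more replicons plus an optional exclusion mask.

    ``excluded_genes`` masks genes (e.g. ribosomal genes) from order
    sampling and from gene-content counting without removing them from the
    coordinate system.
    """

    genome_id: str
    replicons: list[Replicon]
    excluded_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise FormatError(f"genome {self.genome_id!r} has no replicons")
        seen: set[str] = set()
        for rep in self.replicons:
            for locus in rep.loci:
                if locus.gene_id in seen:
                    raise FormatError(
                        f"genome {self.genome_id!r}: duplicate gene_id "
                        f"{locus.gene_id!r}"
                    )
                seen.add(locus.gene_id)
        unknown = self.excluded_genes - seen
        if unknown:
            raise FormatError(
                f"genome {self.genome_id!r}: excluded genes not present: "
                f"{sorted(unknown)[:5]}"
            )

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for rep in self.replicons for g in rep.loci}

    @property
    def n_genes(self) -> int:
        """Number of genes after applying the exclusion mask."""
        return sum(len(rep) for rep in self.replicons) - len(self.excluded_genes)

    def locus(self, gene_id: str) -> GeneLocus:
        for rep in self.replicons:
            for g in rep.loci:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def position_index(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (replicon_id, index) lookup for all genes."""
        return {
            g.gene_id: (rep.replicon_id, g.index)
            for rep in self.replicons
            for g in rep.loci
        }

    def with_exclusions(self, gene_ids: Iterable[str]) -> "GenomeRecord":
        return GenomeRecord(
            genome_id=self.genome_id,
            replicons=self.replicons,
            excluded_genes=self.excluded_genes | set(gene_ids),
        )


@dataclass
class OrthologMap:
    """A one-to-one ortholog mapping between the genes of two genomes."""

    genome_a: str
    genome_b: str
    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def transposed(self) -> "OrthologMap":
        return OrthologMap(
            genome_a=self.genome_b,
            genome_b=self.genome_a,
            pairs={(b, a) for a, b in self.pairs},
        )

    def validate_against(self, a: GenomeRecord, b: GenomeRecord) -> None:
        """Check every gene id resolves to a locus in its genome."""
        ids_a, ids_b = a.gene_ids, b.gene_ids
        for ga, gb in self.pairs:
            if ga not in ids_a:
                raise ValueError(f"{ga!r} not in genome {a.genome_id!r}")
            if gb not in ids_b:
                raise ValueError(f"{gb!r} not in genome {b.genome_id!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["genome_id", "replicon_id", "index", "gene_id", "strand"]


def read_gene_order_table(
    path: str | Path,
    dialect: Literal["tsv", "gff3", "genbank-feature-table"] = "tsv",
) -> GenomeRecord:
    """Read a genome's gene order from a file.

    ``tsv``: columns genome_id, replicon_id, index, gene_id, strand (header
    optional).  ``gff3``/``genbank-feature-table``: CDS features only; the
    ordinal index is the 0-based rank of each CDS by start coordinate on its
    replicon.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "genbank-feature-table":
        return _read_genbank(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> GenomeRecord:
    rows: list[tuple[str, str, int, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[:2] == TSV_COLUMNS[:2]:
                continue  # header
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected ≥4 columns")
            strand = row[4] if len(row) > 4 and row[4] in ("+", "-") else "?"
            try:
                idx = int(row[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad index {row[2]!r}") from exc
            rows.append((row[0], row[1], idx, row[3], strand))
    if not rows:
        raise FormatError(f"{path}: empty gene order table")
    genome_ids = {r[0] for r in rows}
    if len(genome_ids) != 1:
        raise FormatError(f"{path}: multiple genome_ids {sorted(genome_ids)}")
    by_rep: dict[str, list[GeneLocus]] = {}
    seen_pos: set[tuple[str, int]] = set()
    for gid, rid, idx, gene, strand in rows:
        if (rid, idx) in seen_pos:
            raise FormatError(f"{path}: duplicate position ({rid}, {idx})")
        seen_pos.add((rid, idx))
        by_rep.setdefault(rid, []).append(
            GeneLocus(gene_id=gene, replicon_id=rid, index=idx, strand=strand)
        )
    replicons = [Replicon(rid, loci) for rid, loci in sorted(by_rep.items())]
    return GenomeRecord(genome_id=next(iter(genome_ids)), replicons=replicons)


def _read_gff3(path: Path) -> GenomeRecord:
    """CDS features ranked by start coordinate per seqid."""
    features: dict[str, list[tuple[int, str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _, ftype, start, _, _, strand, _, attrs = cols[:9]
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("locus_tag")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: CDS lacks ID/locus_tag")
            features.setdefault(seqid, []).append(
                (int(start), gene_id, strand if strand in "+-" else "?")
            )
    if not features:
        raise FormatError(f"{path}: no CDS features")
    replicons = []
    for seqid in sorted(features):
        feats = sorted(features[seqid])
        loci = [
            GeneLocus(gene_id=g, replicon_id=seqid, index=i, strand=s)
            for i, (_, g, s) in enumerate(feats)
        ]
        replicons.append(Replicon(seqid, loci))
    return GenomeRecord(genome_id=path.stem, replicons=replicons)


def _read_genbank(path: Path) -> GenomeRecord:
    from Bio import SeqIO  # local import: biopython only needed here

    replicons = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene_id = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("protein_id", [None])[0]
            )
            if gene_id is None:
                continue
            strand = "+" if feat.location.strand == 1 else (
                "-" if feat.location.strand == -1 else "?"
            )
            feats.append((int(feat.location.start), gene_id, strand))
        if not feats:
            continue
        feats.sort()
        loci = [
            GeneLocus(gene_id=g, replicon_id=rec.id, index=i, strand=s)
            for i, (_, g, s) in enumerate(feats)
        ]
        replicons.append(
            Replicon(rec.id, loci, circular=rec.annotations.get("topology") == "circular")
        )
    if not replicons:
        raise FormatError(f"{path}: no CDS features in GenBank file")
    return GenomeRecord(genome_id=replicons[0].replicon_id, replicons=replicons)


def read_ortholog_table(
    path: str | Path, genome_a: str, genome_b: str
) -> OrthologMap:
    """Read a two-column TSV of ortholog gene-id pairs."""
    pairs: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[:2] == ["gene_a", "gene_b"]:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            pairs.add((row[0], row[1]))
    return OrthologMap(genome_a=genome_a, genome_b=genome_b, pairs=pairs)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

#: Column order of the BLAST tabular ("outfmt 6") dialect.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path) -> list[tuple[str, str, float]]:
    """Read (query, subject, bitscore) triples from BLAST tabular output."""
    hits = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BLAST columns")
            hits.append((row[0], row[1], float(row[11])))
    return hits


def _unique_best(hits: Iterable[tuple[str, str, float]]) -> dict[str, str]:
    """query -> subject for queries with a unique top-score subject.

    A tie for the top score (exact float equality) disqualifies the query:
    no pair is formed even if one tied subject would reciprocate.
    """
    best: dict[str, tuple[float, str, bool]] = {}  # query -> (score, subject, tied)
    for q, s, score in hits:
        cur = best.get(q)
        if cur is None or score > cur[0]:
            best[q] = (score, s, False)
        elif score == cur[0] and s != cur[1]:
            best[q] = (cur[0], cur[1], True)
    return {q: s for q, (_, s, tied) in best.items() if not tied}


def reciprocal_best_hits(
    hits_ab: Sequence[tuple[str, str, float]],
    hits_ba: Sequence[tuple[str, str, float]],
    genome_a: str = "A",
    genome_b: str = "B",
) -> OrthologMap:
    """Infer one-to-one orthologs from two directed hit tables.

    A pair (a, b) is kept iff b is the unique best-scoring subject for
    query a and a is the unique best-scoring subject for query b.  The
    ranking score is the bitscore, descending.
    """
    queries_ab = {q for q, _, _ in hits_ab}
    queries_ba = {q for q, _, _ in hits_ba}
    overlap = queries_ab & queries_ba
    if overlap:
        raise ValueError(
            f"gene ids appear as queries in both directions (shared id "
            f"spaces?): {sorted(overlap)[:5]}"
        )
    fwd = _unique_best(hits_ab)
    rev = _unique_best(hits_ba)
    pairs = {(a, b) for a, b in fwd.items() if rev.get(b) == a}
    return OrthologMap(genome_a=genome_a, genome_b=genome_b, pairs=pairs)


def restrict_to_replicon(
    genome: GenomeRecord, mode: str = "largest"
) -> GenomeRecord:
    """Keep exactly one replicon: the largest, or a named one.

    ``mode`` is ``"largest"`` or ``"named:<replicon_id>"``.  Ties on length
    are broken lexicographically by replicon id.  The exclusion mask is
    restricted to genes on the kept replicon.
    """
    if mode == "largest":
        chosen = min(genome.replicons, key=lambda r: (-len(r), r.replicon_id))
    elif mode.startswith("named:"):
        name = mode.split(":", 1)[1]
        matches = [r for r in genome.replicons if r.replicon_id == name]
        if not matches:
            raise KeyError(f"replicon {name!r} not in genome {genome.genome_id!r}")
        chosen = matches[0]
    else:
        raise ValueError(f"unknown replicon mode {mode!r}")
    kept_ids = {g.gene_id for g in chosen.loci}
    return GenomeRecord(
        genome_id=genome.genome_id,
        replicons=[chosen],
        excluded_genes=genome.excluded_genes & kept_ids,
    )


def write_gene_order_table(genome: GenomeRecord, path: str | Path) -> None:
    """Write the gene-order TSV the readers consume."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rep in genome.replicons:
            for g in rep.loci:
                writer.writerow(
                    [genome.genome_id, rep.replicon_id, g.index, g.gene_id,
                     g.strand if g.strand in "+-" else "?"]
                )


def write_ortholog_table(orthomap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b"])
        for a, b in sorted(orthomap.pairs):
            writer.writerow([a, b])
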