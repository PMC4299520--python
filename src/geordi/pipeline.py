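"""End-to-end pipeline: distances → matrices → trees → support → subtrees.

A single YAML/dict configuration drives the full analysis: genomes (from
gene-order TSVs or simulated on the fly), pairwise ortholog maps, the
replicate Monte Carlo schedule, matrix assembly and export, the reference
NJ tree with replicate support, agreement subtrees, and the hierarchical
ranked-pair builder.  All randomness flows from the single configured seed
through named substreams, so re-running an identical configuration is
bit-identical; a manifest records every parameter, seed and output.
"""

from __future__ import annotations

import csv
import json
import platform
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

from . import __version__
from .agreement import agreement_subtree_exact, agreement_subtree_heuristic
from .genome_model import (
    GenomeRecord,
    OrthologMap,
    read_gene_order_table,
    read_ortholog_table,
    write_gene_order_table,
    write_ortholog_table,
)
from .hierarchical import add_single_taxa, build_ranked_list, grow_trees
from .matrices_trees import (
    DistanceMatrix,
    PhyloTree,
    assemble_matrix,
    nj_tree,
    support_from_replicates,
    write_newick,
)
from .order_distance import (
    RawEstimate,
    SamplerConfig,
    correct_estimate,
    sample_raw_distance,
)
from .simulate import (
    RearrangementModel,
    evolve_along_tree,
    identity_orthomap,
    random_genome,
)

DISTANCE_TSV_HEADER = [
    "genome_a", "genome_b", "k_fail", "n", "D",
    "D_jc", "D_tajima", "D_log", "seed", "replicate",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see `from_dict` for the schema)."""

    out_dir: Path
    seed: int = 0
    k_genes: int = 6
    min_gap: int = 5
    n_iter: int = 100_000
    n_replicates: int = 100
    correction: str = "tajima"
    m_constant: str | int = "auto"
    replicon_mode: str = "largest"
    genome_paths: list[Path] = field(default_factory=list)
    ortholog_paths: dict[tuple[str, str], Path] = field(default_factory=dict)
    exclude_genes_path: Optional[Path] = None
    simulate: Optional[dict] = None  # n_taxa, n_genes, tree, rate, segment
    agreement_exact_max: int = 12

    @classmethod
    def from_dict(cls, raw: dict, out_dir: str | Path) -> "PipelineConfig":
        cfg = cls(out_dir=Path(out_dir))
        for key in ("seed", "k_genes", "min_gap", "n_iter", "n_replicates",
                    "correction", "m_constant", "replicon_mode",
                    "agreement_exact_max"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if cfg.k_genes not in (5, 6):
            raise ValueError("k_genes must be 5 or 6")
        if cfg.n_iter < 1 or cfg.n_replicates < 1:
            raise ValueError("n_iter and n_replicates must be ≥ 1")
        for p in raw.get("genomes", []):
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(path)
            cfg.genome_paths.append(path)
        for entry in raw.get("orthologs", []):
            path = Path(entry["path"])
            if not path.exists():
                raise FileNotFoundError(path)
            cfg.ortholog_paths[(entry["genome_a"], entry["genome_b"])] = path
        if raw.get("exclude_genes"):
            cfg.exclude_genes_path = Path(raw["exclude_genes"])
        cfg.simulate = raw.get("simulate")
        return cfg

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            k_genes=self.k_genes,
            min_gap=self.min_gap,
            n_iter=self.n_iter,
            n_replicates=self.n_replicates,
            seed=self.seed,
            replicon_mode=self.replicon_mode,
            m_constant=self.m_constant,
        )


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[list[GenomeRecord], dict[tuple[str, str], OrthologMap]]:
    if cfg.simulate:
        sim = cfg.simulate
        tree = PhyloTree.from_newick(sim["tree"])
        root = random_genome(int(sim.get("n_genes", 1000)), "root",
                             seed=cfg.seed)
        model = RearrangementModel(
            segment_length=sim.get("segment_length", "geometric:0.1"),
            events_rate=float(sim.get("events_rate", 100.0)),
        )
        genomes, _ = evolve_along_tree(tree, root, model, seed=cfg.seed)
        sim_dir = cfg.out_dir / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        for gen in genomes:
            write_gene_order_table(gen, sim_dir / f"{gen.genome_id}.tsv")
        maps = {}
        for a, b in combinations(sorted(genomes, key=lambda x: x.genome_id), 2):
            om = identity_orthomap(a, b)
            maps[(a.genome_id, b.genome_id)] = om
            write_ortholog_table(
                om, sim_dir / f"{a.genome_id}__{b.genome_id}.orthologs.tsv"
            )
        return sorted(genomes, key=lambda x: x.genome_id), maps

    genomes = [read_gene_order_table(p) for p in cfg.genome_paths]
    genomes.sort(key=lambda x: x.genome_id)
    if cfg.exclude_genes_path is not None:
        excluded = {
            line.strip()
            for line in cfg.exclude_genes_path.read_text().splitlines()
            if line.strip()
        }
        genomes = [
            gen.with_exclusions(excluded & gen.gene_ids) for gen in genomes
        ]
    ids = [gen.genome_id for gen in genomes]
    maps = {}
    missing = []
    for a, b in combinations(ids, 2):
        path = cfg.ortholog_paths.get((a, b)) or cfg.ortholog_paths.get((b, a))
        if path is None:
            missing.append((a, b))
            continue
        key = (a, b) if (a, b) in cfg.ortholog_paths else (b, a)
        maps[(a, b)] = (
            read_ortholog_table(path, *key).transposed()
            if key == (b, a)
            else read_ortholog_table(path, a, b)
        )
    if missing:
        raise ValueError(f"missing ortholog maps for pairs: {missing}")
    return genomes, maps


def _write_distance_tsv(
    path: Path, estimates: list[RawEstimate], m: int
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DISTANCE_TSV_HEADER)
        for e in estimates:
            writer.writerow([
                e.genome_pair[0], e.genome_pair[1], e.k_fail, e.n,
                f"{e.D:.8f}",
                f"{correct_estimate(e, 'jc', m).value:.8f}",
                f"{correct_estimate(e, 'tajima', m).value:.8f}",
                f"{correct_estimate(e, 'logcorr', m).value:.8f}",
                e.seed, e.replicate_index,
            ])


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Outputs: per-replicate distance TSVs, pooled matrix (PHYLIP + NEXUS),
    reference NJ Newick with replicate support, agreement-subtree Newick +
    taxon TSV, hierarchical ledger TSV, and ``manifest.json``.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    genomes, maps = _load_inputs(cfg)
    scfg = cfg.sampler_config()
    m = scfg.m

    estimates: list[RawEstimate] = []
    rep_dir = out / "replicates"
    rep_dir.mkdir(exist_ok=True)
    for rep in range(cfg.n_replicates):
        rep_estimates = []
        for (a_id, b_id), om in sorted(maps.items()):
            a = next(gen for gen in genomes if gen.genome_id == a_id)
            b = next(gen for gen in genomes if gen.genome_id == b_id)
            rep_estimates.append(
                sample_raw_distance(a, b, om, scfg, replicate_index=rep)
            )
        _write_distance_tsv(
            rep_dir / f"distances_rep{rep:03d}.tsv", rep_estimates, m
        )
        estimates.extend(rep_estimates)

    pooled = assemble_matrix(estimates, correction=cfg.correction,
                             combine="pooled", m=m)
    per_rep = assemble_matrix(estimates, correction=cfg.correction,
                              combine="per_replicate", m=m)
    pooled.to_phylip(out / "pooled.phylip")
    pooled.to_nexus(out / "pooled.nex")

    outputs = {
        "pooled_matrix": "pooled.phylip",
        "pooled_nexus": "pooled.nex",
        "replicate_dir": "replicates",
    }
    n_taxa = len(pooled.taxa)
    if n_taxa >= 3 and not pooled.has_undefined:
        reference = nj_tree(pooled)
        replicate_trees = [
            nj_tree(mat) for mat in per_rep if not mat.has_undefined
        ]
        supported = support_from_replicates(reference, replicate_trees)
        write_newick(supported, out / "reference_nj.nwk")
        with open(out / "replicate_trees.nwk", "w") as fh:
            for t in replicate_trees:
                fh.write(t.to_newick() + "\n")
        outputs["reference_tree"] = "reference_nj.nwk"
        outputs["replicate_trees"] = "replicate_trees.nwk"

        if len(replicate_trees) >= 2 and n_taxa >= 4:
            if n_taxa <= cfg.agreement_exact_max:
                results = agreement_subtree_exact(
                    replicate_trees, max_taxa=cfg.agreement_exact_max
                )
            else:
                results = [agreement_subtree_heuristic(replicate_trees)]
            with open(out / "agreement_taxa.tsv", "w", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["subtree_index", "n_taxa", "taxa"])
                for i, (taxa, _) in enumerate(results):
                    writer.writerow([i, len(taxa), ",".join(sorted(taxa))])
            with open(out / "agreement_trees.nwk", "w") as fh:
                for _, t in results:
                    fh.write(t.to_newick() + "\n")
            outputs["agreement_taxa"] = "agreement_taxa.tsv"
            outputs["agreement_trees"] = "agreement_trees.nwk"

        ranked = build_ranked_list(pooled)
        ledger = grow_trees(ranked, pooled)
        with open(out / "hierarchical_ledger.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["formation_rank", "last_rank", "taxa", "newick"])
            for row in ledger.to_rows():
                writer.writerow(row)
        outputs["hierarchical_ledger"] = "hierarchical_ledger.tsv"
        largest = ledger.largest
        if largest is not None and len(largest.taxon_set) >= 4:
            final = add_single_taxa(largest.tree, pooled, ranked)
            write_newick(final, out / "hierarchical_final.nwk")
            outputs["hierarchical_final"] = "hierarchical_final.nwk"

    manifest = {
        "geordi_version": __version__,
        "python_version": platform.python_version(),
        "parameters": {
            "seed": cfg.seed,
            "k_genes": cfg.k_genes,
            "min_gap": cfg.min_gap,
            "n_iter": cfg.n_iter,
            "n_replicates": cfg.n_replicates,
            "correction": cfg.correction,
            "m_constant": str(cfg.m_constant),
            "m": m,
            "replicon_mode": cfg.replicon_mode,
            "simulate": cfg.simulate,
        },
        "taxa": [gen.genome_id for gen in genomes],
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
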