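"""End-to-end orchestration: predict -> align -> score -> families -> stats.

Thin glue over the stage modules so the CLI, the analysis drivers and
the tests all run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .align import HitTable, all_vs_all
from .families import (
    FamilyConfig, FamilyStats, SMGCFamily, detect_families,
    family_statistics, shared_cluster_matrix,
)
from .model import AnnotatedGenome
from .predict import SMGC, PredictorConfig, backbone_census, predict_clusters
from .score import ClusterPairScore, ScoringConfig, SMGCNetwork, build_network


def gene_protein_map(genomes: list[AnnotatedGenome]) -> dict[str, str]:
    out: dict[str, str] = {}
    for genome in genomes:
        for genes in genome.genes.values():
            for g in genes:
                out[g.gene_id] = g.protein_id
    return out


def cluster_proteomes(
    genomes: list[AnnotatedGenome], clusters: list[SMGC]
) -> dict[str, dict[str, str]]:
    """Per-species proteome restricted to cluster member genes."""
    by_species = {g.species_id: g for g in genomes}
    g2p = gene_protein_map(genomes)
    out: dict[str, dict[str, str]] = {g.species_id: {} for g in genomes}
    for c in clusters:
        genome = by_species[c.species_id]
        for gid in c.gene_ids:
            pid = g2p[gid]
            out[c.species_id][pid] = genome.proteins[pid]
    return out


@dataclass
class PipelineResult:
    clusters: list[SMGC]
    hits: HitTable
    network: SMGCNetwork
    scores: list[ClusterPairScore]
    families: list[SMGCFamily]
    stats: FamilyStats
    shared_matrix: pd.DataFrame
    census: pd.DataFrame
    gene_to_protein: dict[str, str] = field(default_factory=dict)

    @property
    def cluster_species(self) -> dict[str, str]:
        return {c.cluster_id: c.species_id for c in self.clusters}


def run_pipeline(
    genomes: list[AnnotatedGenome],
    predictor_config: PredictorConfig | None = None,
    scoring_config: ScoringConfig | None = None,
    family_config: FamilyConfig | None = None,
) -> PipelineResult:
    """Predict clusters in every genome, score all pairs, detect families."""
    scoring_config = scoring_config or ScoringConfig()
    clusters: list[SMGC] = []
    for genome in genomes:
        clusters.extend(predict_clusters(genome, predictor_config))
    g2p = gene_protein_map(genomes)
    proteomes = cluster_proteomes(genomes, clusters)
    hits = all_vs_all(proteomes, evalue_cutoff=scoring_config.evalue_cutoff)
    network, scores = build_network(clusters, hits, g2p, scoring_config)
    families = detect_families(network, family_config)
    cluster_species = {c.cluster_id: c.species_id for c in clusters}
    stats = family_statistics(families, cluster_species)
    shared = shared_cluster_matrix(families, cluster_species)
    census = backbone_census(clusters)
    return PipelineResult(
        clusters=clusters, hits=hits, network=network, scores=scores,
        families=families, stats=stats, shared_matrix=shared, census=census,
        gene_to_protein=g2p,
    )


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write all stage tables with deterministic content."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clusters": out_dir / "clusters.tsv",
        "scores": out_dir / "scores.tsv",
        "families": out_dir / "families.tsv",
        "shared_matrix": out_dir / "shared_matrix.tsv",
        "census": out_dir / "backbone_census.tsv",
        "hits": out_dir / "hits.tsv",
    }
    io.write_cluster_table(result.clusters, paths["clusters"])
    io.write_score_table(result.scores, paths["scores"])
    io.write_family_table(result.families, paths["families"])
    io.write_shared_matrix(result.shared_matrix, paths["shared_matrix"])
    result.census.to_csv(paths["census"], sep="\t")
    result.hits.write(paths["hits"])
    return paths
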