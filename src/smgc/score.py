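"""Cluster-pair similarity score and the weighted SMGC network.

The score between two clusters combines a tailoring term and a backbone
term.  For each role the percent identities of matched enzyme pairs are
summed, divided by the larger of the two clusters' enzyme counts for
that role (nmax), and weighted 0.3 (tailoring) / 0.7 (backbone):

    score = sum(pident_tailoring)/nmax_tailoring * 0.3
          + sum(pident_backbone)/nmax_backbone * 0.7

Hits are reduced to a maximum-weight one-to-one pairing per role, which
bounds the score at 100 and makes a cluster score exactly 100 against
itself.  When both clusters lack tailoring enzymes the backbone weight
is renormalised to 1.0; when only one lacks them the tailoring term is
zero with nmax taken from the other cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .align import HitTable
from .predict import SMGC


@dataclass
class ScoringConfig:
    w_tailoring: float = 0.3
    w_backbone: float = 0.7
    evalue_cutoff: float = 1e-10
    pairing_policy: str = "optimal_one_to_one"  # or "best_hit_per_query"
    edge_threshold: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.w_tailoring + self.w_backbone - 1.0) > 1e-9:
            raise ValueError("w_tailoring + w_backbone must equal 1")


@dataclass(frozen=True)
class ClusterPairScore:
    cluster_a: str
    cluster_b: str
    sum_pident_tailoring: float
    nmax_tailoring: int
    sum_pident_backbone: float
    nmax_backbone: int
    score_tailoring: float
    score_backbone: float
    total: float


def _role_proteins(cluster: SMGC, gene_to_protein: dict[str, str]) -> tuple[list[str], list[str]]:
    backbone = [gene_to_protein[g] for g in cluster.backbone_gene_ids]
    tailoring = [gene_to_protein[g] for g in cluster.tailoring_gene_ids]
    return backbone, tailoring


def _pident_matrix(ids_a: list[str], ids_b: list[str], hits: HitTable) -> np.ndarray:
    mat = np.zeros((len(ids_a), len(ids_b)))
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            mat[i, j] = hits.pident(a, b)
    return mat


def _matched_sum(mat: np.ndarray, policy: str) -> float:
    if mat.size == 0:
        return 0.0
    if policy == "optimal_one_to_one":
        rows, cols = linear_sum_assignment(mat, maximize=True)
        return float(mat[rows, cols].sum())
    if policy == "best_hit_per_query":
        return float(mat.max(axis=1).sum())
    raise ValueError(f"unknown pairing policy {policy!r}")


def exhaustive_matched_sum(mat: np.ndarray) -> float:
    """Brute-force maximum over all injective pairings (oracle for tests)."""
    n, m = mat.shape
    if n == 0 or m == 0:
        return 0.0
    if n > m:
        return exhaustive_matched_sum(mat.T)
    best = 0.0
    for cols in itertools.permutations(range(m), n):
        best = max(best, sum(mat[i, c] for i, c in enumerate(cols)))
    return best


def score_pair(
    a: SMGC,
    b: SMGC,
    hits: HitTable,
    gene_to_protein: dict[str, str],
    config: ScoringConfig | None = None,
) -> ClusterPairScore:
    """Score one cluster pair from the symmetrised best-hit table."""
    config = config or ScoringConfig()
    for c in (a, b):
        if not c.backbones:
            raise ValueError(f"cluster {c.cluster_id} has no backbone gene")
    bb_a, tail_a = _role_proteins(a, gene_to_protein)
    bb_b, tail_b = _role_proteins(b, gene_to_protein)

    sum_bb = _matched_sum(_pident_matrix(bb_a, bb_b, hits), config.pairing_policy)
    nmax_bb = max(len(bb_a), len(bb_b))
    sum_tail = _matched_sum(_pident_matrix(tail_a, tail_b, hits), config.pairing_policy)
    nmax_tail = max(len(tail_a), len(tail_b))

    w_tail, w_bb = config.w_tailoring, config.w_backbone
    if nmax_tail == 0:
        # both clusters tailoring-free: all weight on the backbone term
        w_tail, w_bb = 0.0, 1.0
        score_tail = 0.0
    else:
        score_tail = sum_tail / nmax_tail * w_tail
    score_bb = sum_bb / nmax_bb * w_bb
    return ClusterPairScore(
        cluster_a=a.cluster_id,
        cluster_b=b.cluster_id,
        sum_pident_tailoring=sum_tail,
        nmax_tailoring=nmax_tail,
        sum_pident_backbone=sum_bb,
        nmax_backbone=nmax_bb,
        score_tailoring=score_tail,
        score_backbone=score_bb,
        total=score_tail + score_bb,
    )


@dataclass
class SMGCNetwork:
    """Weighted undirected network over predicted clusters."""

    graph: nx.Graph
    species_of: dict[str, str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    clusters: list[SMGC],
    hits: HitTable,
    gene_to_protein: dict[str, str],
    config: ScoringConfig | None = None,
) -> tuple[SMGCNetwork, list[ClusterPairScore]]:
    """Score all cluster pairs and keep edges above the threshold.

    Isolated clusters stay in the node set so downstream community
    detection sees them as singleton families.
    """
    config = config or ScoringConfig()
    g = nx.Graph()
    ordered = sorted(clusters, key=lambda c: c.cluster_id)
    for c in ordered:
        g.add_node(c.cluster_id)
    scores: list[ClusterPairScore] = []
    for a, b in itertools.combinations(ordered, 2):
        s = score_pair(a, b, hits, gene_to_protein, config)
        scores.append(s)
        if s.total > config.edge_threshold:
            g.add_edge(a.cluster_id, b.cluster_id, weight=s.total)
    species_of = {c.cluster_id: c.species_id for c in clusters}
    return SMGCNetwork(graph=g, species_of=species_of), scores
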