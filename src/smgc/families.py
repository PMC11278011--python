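"""Collapse the cluster similarity network into families.

Communities are found by the walktrap algorithm (short random walks on
the weighted graph followed by agglomerative merging, cut at maximal
modularity).  Any community with more members than there are species in
the analysis is re-clustered once by an identical round on its induced
subgraph; a community still oversized after that is accepted with a
warning.  Isolated clusters become singleton-member families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import pandas as pd

from .score import SMGCNetwork

log = logging.getLogger(__name__)


@dataclass
class FamilyConfig:
    walk_steps: int = 4
    max_members: int | None = None  # None: number of species in the network

    def __post_init__(self) -> None:
        if self.walk_steps < 1:
            raise ValueError("walk_steps must be >= 1")


@dataclass
class SMGCFamily:
    family_id: str
    cluster_ids: tuple[str, ...]
    species_of_members: tuple[str, ...]
    compound_labels: tuple[str, ...] = ()

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(self.species_of_members)

    @property
    def singleton(self) -> bool:
        return len(self.species_set) == 1


@dataclass
class FamilyStats:
    n_families: int
    n_singleton_families: int
    unique_families_per_species: dict[str, int]
    clusters_per_species: dict[str, int]


def _walktrap_partition(node_ids: list[str], edges: list[tuple[str, str, float]], steps: int) -> list[list[str]]:
    """Walktrap communities as lists of node ids; deterministic via sorted construction."""
    node_ids = sorted(node_ids)
    g = ig.Graph()
    g.add_vertices(len(node_ids))
    index = {n: i for i, n in enumerate(node_ids)}
    edges = sorted(edges)
    if edges:
        g.add_edges([(index[a], index[b]) for a, b, _ in edges])
        g.es["weight"] = [w for _, _, w in edges]
        clustering = g.community_walktrap(weights="weight", steps=steps).as_clustering()
        membership = clustering.membership
    else:
        membership = list(range(len(node_ids)))
    groups: dict[int, list[str]] = {}
    for node, m in zip(node_ids, membership):
        groups.setdefault(m, []).append(node)
    return [sorted(g_) for g_ in groups.values()]


def detect_families(network: SMGCNetwork, config: FamilyConfig | None = None) -> list[SMGCFamily]:
    """Partition the network into families, refining oversized communities once."""
    config = config or FamilyConfig()
    n_species = len(set(network.species_of.values()))
    max_members = config.max_members if config.max_members is not None else n_species

    nodes = sorted(network.graph.nodes)
    edges = [(a, b, d["weight"]) for a, b, d in network.graph.edges(data=True)]
    communities = _walktrap_partition(nodes, edges, config.walk_steps)

    refined: list[list[str]] = []
    for comm in communities:
        if len(comm) <= max_members:
            refined.append(comm)
            continue
        members = set(comm)
        sub_edges = [(a, b, w) for a, b, w in edges if a in members and b in members]
        parts = _walktrap_partition(comm, sub_edges, config.walk_steps)
        for p in parts:
            if len(p) > max_members:
                log.warning(
                    "community of %d members still exceeds %d after refinement",
                    len(p), max_members,
                )
        refined.extend(parts)

    refined.sort(key=lambda members: members[0])
    families = []
    for i, members in enumerate(refined, start=1):
        families.append(
            SMGCFamily(
                family_id=f"F{i:04d}",
                cluster_ids=tuple(members),
                species_of_members=tuple(network.species_of[m] for m in members),
            )
        )
    return families


def _check_partition(families: list[SMGCFamily], all_cluster_ids: set[str]) -> None:
    seen: set[str] = set()
    for fam in families:
        for cid in fam.cluster_ids:
            if cid in seen:
                raise ValueError(f"cluster {cid} appears in more than one family")
            seen.add(cid)
    if seen != all_cluster_ids:
        raise ValueError("families do not cover all clusters")


def family_statistics(
    families: list[SMGCFamily], cluster_species: dict[str, str]
) -> FamilyStats:
    """Totals, singleton count and per-species unique-family/cluster counts.

    ``cluster_species`` maps every cluster id in the analysis to its
    species; the families must partition exactly that cluster set.
    """
    _check_partition(families, set(cluster_species))
    species = sorted(set(cluster_species.values()))
    unique = {s: 0 for s in species}
    per_species_clusters = {s: 0 for s in species}
    for cid, sp in cluster_species.items():
        per_species_clusters[sp] += 1
    n_singleton = 0
    for fam in families:
        if fam.singleton:
            n_singleton += 1
            unique[next(iter(fam.species_set))] += 1
    return FamilyStats(
        n_families=len(families),
        n_singleton_families=n_singleton,
        unique_families_per_species=unique,
        clusters_per_species=per_species_clusters,
    )


def shared_cluster_matrix(
    families: list[SMGCFamily], cluster_species: dict[str, str]
) -> pd.DataFrame:
    """Directional percentage of shared clusters between species pairs.

    Entry (A, B) is the percentage of A's clusters whose family also
    contains at least one cluster from B; the diagonal is 100.
    """
    _check_partition(families, set(cluster_species))
    species = sorted(set(cluster_species.values()))
    family_species = {f.family_id: f.species_set for f in families}
    family_of = {
        cid: f.family_id for f in families for cid in f.cluster_ids
    }
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for a in species:
        a_clusters = [cid for cid, sp in cluster_species.items() if sp == a]
        if not a_clusters:
            continue
        for b in species:
            shared = sum(
                1 for cid in a_clusters if b in family_species[family_of[cid]]
            )
            mat.loc[a, b] = 100.0 * shared / len(a_clusters)
    mat.index.name = "species"
    return mat
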