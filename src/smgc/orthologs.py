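"""Best-bidirectional-hit ortholog groups and monocore export.

For every species pair, two proteins are best bidirectional hits (BBH)
when each is the other's best-scoring hit.  Ties at the top score count
as multiple best hits, so an exact duplicate in one species makes the
group ambiguous for that species.  Groups form by single-linkage over
BBH edges and species represented more than once in a group are
dropped from it.  Monocore groups (exactly one member in every
species) feed the concatenated supermatrix exported for external
alignment and tree inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .align import HitTable, all_vs_all


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, str]  # species_id -> protein_id
    monocore: bool


def _hit_index(hits: HitTable) -> dict[str, list]:
    index: dict[str, list] = {}
    for h in hits:
        index.setdefault(h.query_id, []).append(h)
    return index


def _best_hits(index: dict[str, list], query: str, subjects: set[str]) -> set[str]:
    """Subjects attaining the maximal raw score from ``query`` (ties kept)."""
    scored = [
        (h.raw_score, h.subject_id)
        for h in index.get(query, [])
        if h.subject_id in subjects
    ]
    if not scored:
        return set()
    top = max(s for s, _ in scored)
    return {sid for s, sid in scored if s == top}


def best_bidirectional_hits(
    proteomes: dict[str, dict[str, str]],
    evalue_cutoff: float = 1e-5,
    hits: HitTable | None = None,
) -> list[OrthologGroup]:
    """BBH ortholog groups over >=2 proteomes.

    ``hits`` may be supplied to reuse a precomputed all-vs-all table;
    otherwise it is computed here at the given cutoff.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes for BBH")
    if hits is None:
        hits = all_vs_all(proteomes, evalue_cutoff=evalue_cutoff)
    species_of = {
        pid: sp for sp, prots in proteomes.items() for pid in prots
    }
    members_of = {sp: set(prots) for sp, prots in proteomes.items()}

    index = _hit_index(hits)
    g = nx.Graph()
    g.add_nodes_from(species_of)
    for sp_a, sp_b in itertools.combinations(sorted(proteomes), 2):
        for pid in sorted(members_of[sp_a]):
            for best in _best_hits(index, pid, members_of[sp_b]):
                if pid in _best_hits(index, best, members_of[sp_a]):
                    g.add_edge(pid, best)

    groups: list[OrthologGroup] = []
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    n_species = len(proteomes)
    for i, comp in enumerate(components, start=1):
        by_species: dict[str, list[str]] = {}
        for pid in comp:
            by_species.setdefault(species_of[pid], []).append(pid)
        members = {
            sp: pids[0] for sp, pids in by_species.items() if len(pids) == 1
        }
        groups.append(
            OrthologGroup(
                group_id=f"OG{i:05d}",
                members=members,
                monocore=len(members) == n_species,
            )
        )
    return groups


def _mean_pairwise_pident(group: OrthologGroup, hits: HitTable) -> float:
    pids = sorted(group.members.values())
    pairs = list(itertools.combinations(pids, 2))
    if not pairs:
        return 0.0
    return sum(hits.pident(a, b) for a, b in pairs) / len(pairs)


def select_monocore(
    groups: list[OrthologGroup], hits: HitTable, n: int = 200
) -> list[OrthologGroup]:
    """The ``n`` most conserved monocore groups (mean pairwise identity).

    Ties break by group id; the result is independent of input order.
    """
    monocore = [g for g in groups if g.monocore]
    if len(monocore) < n:
        raise ValueError(
            f"only {len(monocore)} monocore groups available, {n} requested"
        )
    ranked = sorted(
        monocore,
        key=lambda g: (-_mean_pairwise_pident(g, hits), g.group_id),
    )
    return ranked[:n]


def concatenate_monocore(
    groups: list[OrthologGroup], proteomes: dict[str, dict[str, str]]
) -> dict[str, str]:
    """Concatenate each species' members in sorted group order."""
    if not groups:
        raise ValueError("no groups to concatenate")
    species = sorted(proteomes)
    out = {sp: [] for sp in species}
    for group in sorted(groups, key=lambda g: g.group_id):
        for sp in species:
            if sp not in group.members:
                raise ValueError(f"group {group.group_id} lacks species {sp}")
            pid = group.members[sp]
            out[sp].append(proteomes[sp][pid])
    return {sp: "".join(parts) for sp, parts in out.items()}


def write_concatenated_fasta(concatenated: dict[str, str], path: str | Path) -> None:
    """One record per species, plus a comment documenting downstream tools.

    The exported supermatrix is the input for external MAFFT alignment,
    Gblocks extraction (-t = p -b4 = 5 -b5 = h) and RAxML tree building
    (PROTGAMMAWAG, 100 bootstraps); those runs are outside this package.
    """
    with open(path, "w") as fh:
        for sp in sorted(concatenated):
            fh.write(f">{sp}\n")
            seq = concatenated[sp]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_group_table(groups: list[OrthologGroup], path: str | Path) -> None:
    rows = [
        (g.group_id, sp, pid, g.monocore)
        for g in sorted(groups, key=lambda g: g.group_id)
        for sp, pid in sorted(g.members.items())
    ]
    pd.DataFrame(
        rows, columns=["group_id", "species", "protein_id", "monocore"]
    ).to_csv(path, sep="\t", index=False)
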