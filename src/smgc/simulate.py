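"""Synthetic annotated pangenomes with planted cluster families.

Each planted family has a prototype cluster (one backbone gene with the
PFAM composition of its class plus tailoring genes carrying SM-specific
domains) that is copied into every species where the family is present,
with proteins mutated by substitutions only to a controlled percent
identity.  Background genes carry neither SM-specific PFAMs nor a
backbone composition, and the gaps flanking every planted cluster
exceed the 3 kb predictor limit, so the true cluster extents are
unambiguous and every downstream stage can be checked against an exact
truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AnnotatedGenome, DomainHit, GeneModel

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

BACKBONE_COMPOSITIONS: dict[str, tuple[str, ...]] = {
    "PKS": ("PF00109", "PF02801", "PF00698", "PF00550"),
    "PKS-like": ("PF00109", "PF02801", "PF00067"),
    "NRPS": ("PF00668", "PF00501", "PF00550"),
    "NRPS-like": ("PF00668", "PF00501", "PF00975"),
    "HYBRID": ("PF00109", "PF02801", "PF00698", "PF00668", "PF00501", "PF00550"),
    "DMATS": ("PF11991",),
    "TC": ("PF06330",),
}

# SM-specific domains for tailoring genes; disjoint from every
# accession used by the backbone rule table so planted tailoring genes
# can never be classified as backbones.
TAILORING_POOL = (
    "PF00067", "PF01494", "PF08241", "PF00891",
    "PF00106", "PF00583", "PF01593", "PF03171",
)

# neutral accessions for background genes: valid PFAM format, absent
# from both the SM-specific set and the backbone rules
NEUTRAL_POOL = tuple(f"PF9{i:04d}" for i in range(1, 13))


@dataclass
class SimConfig:
    """Study conditions of the synthetic pangenome."""

    n_species: int = 6
    scaffolds_per_genome: int = 2
    genes_per_scaffold: int = 30
    n_planted_families: int = 12
    family_presence: list[list[int]] | float | None = None
    backbone_class_mix: dict[str, float] | None = None
    tailoring_genes_per_cluster: tuple[int, int] = (2, 4)
    intra_cluster_gap_bp: tuple[int, int] = (50, 1500)
    background_gap_bp: tuple[int, int] = (150, 2800)
    flank_gap_bp: tuple[int, int] = (3100, 6000)
    target_identity: float = 85.0
    protein_length: tuple[int, int] = (120, 240)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "scaffolds_per_genome", "genes_per_scaffold",
                     "n_planted_families"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.target_identity <= 100.0:
            raise ValueError("target_identity must be in [0, 100]")
        if self.backbone_class_mix is None:
            self.backbone_class_mix = {c: 1 / 7 for c in BACKBONE_COMPOSITIONS}
        if self.flank_gap_bp[0] <= 3000:
            raise ValueError("flank gaps must exceed the 3 kb predictor limit")


@dataclass(frozen=True)
class PlantedCluster:
    species_id: str
    family_label: str
    scaffold: str
    gene_ids: tuple[str, ...]
    backbone_gene_id: str
    backbone_class: str
    tailoring_gene_ids: tuple[str, ...]


@dataclass
class TruthTable:
    """Exact ground truth of the planted design."""

    clusters: list[PlantedCluster] = field(default_factory=list)

    def extent_map(self) -> dict[tuple[str, frozenset[str]], PlantedCluster]:
        return {(c.species_id, frozenset(c.gene_ids)): c for c in self.clusters}

    def family_of_species(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for c in self.clusters:
            out.setdefault(c.family_label, set()).add(c.species_id)
        return out

    def n_singleton_families(self) -> int:
        return sum(1 for sp in self.family_of_species().values() if len(sp) == 1)

    def backbone_census(self) -> pd.DataFrame:
        species = sorted({c.species_id for c in self.clusters})
        census = pd.DataFrame(0, index=species, columns=list(BACKBONE_COMPOSITIONS))
        for c in self.clusters:
            census.loc[c.species_id, c.backbone_class] += 1
        census.index.name = "species"
        return census

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.family_label, c.species_id, c.scaffold, ";".join(c.gene_ids),
             c.backbone_gene_id, c.backbone_class)
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["family", "species", "scaffold", "gene_ids",
                     "backbone_gene", "backbone_class"],
        ).sort_values(["family", "species"], kind="mergesort")

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mutate_protein(seq: str, target_identity: float, seed) -> str:
    """Substitute exactly ``floor((100 - identity)/100 * len)`` positions.

    Length-preserving; substitutions are drawn uniformly from the 19
    alternative residues.  ``seed`` may be an int or a Generator.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 <= target_identity <= 100.0:
        raise ValueError("target_identity must be in [0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(np.floor((100.0 - target_identity) / 100.0 * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = AMINO_ACIDS[AMINO_ACIDS != chars[pos]]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def per_copy_identity(pairwise_identity: float) -> float:
    """Per-copy identity to the family prototype giving the desired
    pairwise identity between two independently mutated copies.

    Two copies agree at a position with probability
    ``(1-d)^2 + d^2/19`` when each substitutes a fraction ``d`` of
    positions independently and uniformly over the 19 alternatives;
    solving for ``d`` keeps the *pairwise* cross-genome identity on
    target rather than the copy-to-prototype identity.
    """
    t = pairwise_identity / 100.0
    discriminant = 1.0 - (20.0 / 19.0) * (1.0 - t)
    if discriminant <= 0.0:  # below the random-divergence floor
        d = 19.0 / 20.0
    else:
        d = (1.0 - np.sqrt(discriminant)) * 19.0 / 20.0
    return 100.0 * (1.0 - d)


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(AMINO_ACIDS, size=n))


@dataclass
class _Prototype:
    family_label: str
    backbone_class: str
    order: list[int]  # position of the backbone among members
    proteins: list[str]  # index 0 = backbone, then tailoring
    domains: list[tuple[str, ...]]
    present_in: list[int]


def _draw_presence(cfg: SimConfig, rng: np.random.Generator) -> list[list[int]]:
    if isinstance(cfg.family_presence, list):
        return [sorted(set(p)) for p in cfg.family_presence]
    presence = []
    for _ in range(cfg.n_planted_families):
        if isinstance(cfg.family_presence, float):
            members = [i for i in range(cfg.n_species)
                       if rng.random() < cfg.family_presence]
            if not members:
                members = [int(rng.integers(cfg.n_species))]
        else:
            # default design: a quarter of families are planted singletons,
            # the rest span a uniform 2..n_species subset
            if cfg.n_species == 1 or rng.random() < 0.25:
                k = 1
            else:
                k = int(rng.integers(2, cfg.n_species + 1))
            members = sorted(rng.choice(cfg.n_species, size=k, replace=False).tolist())
        presence.append(members)
    return presence


def _make_prototypes(cfg: SimConfig, rng: np.random.Generator) -> list[_Prototype]:
    classes = sorted(cfg.backbone_class_mix)
    probs = np.array([cfg.backbone_class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    presence = _draw_presence(cfg, rng)
    if len(presence) != cfg.n_planted_families:
        raise ValueError("family_presence length must equal n_planted_families")
    prototypes = []
    for f, present in enumerate(presence):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        n_tail = int(rng.integers(cfg.tailoring_genes_per_cluster[0],
                                  cfg.tailoring_genes_per_cluster[1] + 1))
        proteins = [_random_protein(rng, cfg.protein_length) for _ in range(1 + n_tail)]
        domains: list[tuple[str, ...]] = [BACKBONE_COMPOSITIONS[cls]]
        for _ in range(n_tail):
            k = int(rng.integers(1, 3))
            accs = rng.choice(len(TAILORING_POOL), size=k, replace=False)
            domains.append(tuple(TAILORING_POOL[i] for i in sorted(accs)))
        order = rng.permutation(1 + n_tail).tolist()
        prototypes.append(
            _Prototype(
                family_label=f"fam{f:03d}", backbone_class=cls, order=order,
                proteins=proteins, domains=domains, present_in=present,
            )
        )
    return prototypes


def generate_pangenome(config: SimConfig) -> tuple[list[AnnotatedGenome], TruthTable]:
    """Generate all genomes of the design plus the exact truth table."""
    rng = np.random.default_rng(config.seed)
    prototypes = _make_prototypes(config, rng)
    truth = TruthTable()
    genomes = []
    for s in range(config.n_species):
        species_id = f"sp{s:02d}"
        fams = [p for p in prototypes if s in p.present_in]
        budget = config.scaffolds_per_genome * max(1, config.genes_per_scaffold // 2)
        if len(fams) > budget:
            raise ValueError(
                f"{species_id}: cannot pack {len(fams)} clusters into "
                f"{config.scaffolds_per_genome} scaffolds"
            )
        genomes.append(_build_genome(species_id, fams, config, rng, truth))
    return genomes, truth


def _build_genome(
    species_id: str,
    fams: list[_Prototype],
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: TruthTable,
) -> AnnotatedGenome:
    genome = AnnotatedGenome(species_id=species_id)
    scaffold_of_fam = rng.integers(cfg.scaffolds_per_genome, size=len(fams))
    gene_counter = 0
    for sc in range(cfg.scaffolds_per_genome):
        scaffold = f"{species_id}_sc{sc:02d}"
        fam_here = [f for f, assigned in zip(fams, scaffold_of_fam) if assigned == sc]
        n_bg = cfg.genes_per_scaffold
        # choose background-gene indices after which each cluster is inserted
        slots = sorted(rng.choice(n_bg, size=len(fam_here), replace=False).tolist())
        genes: list[GeneModel] = []
        cursor = int(rng.integers(500, 2000))
        cluster_at = dict(zip(slots, fam_here))
        for i in range(n_bg):
            gene_counter, cursor = _emit_background_gene(
                genome, genes, scaffold, species_id, gene_counter, cursor, cfg, rng
            )
            if i in cluster_at:
                gene_counter, cursor = _emit_cluster(
                    genome, genes, scaffold, species_id, gene_counter, cursor,
                    cluster_at[i], cfg, rng, truth,
                )
        genome.genes[scaffold] = genes
    return genome.validate()


def _next_gap(rng, gap_range: tuple[int, int]) -> int:
    return int(rng.integers(gap_range[0], gap_range[1] + 1))


def _emit_background_gene(genome, genes, scaffold, species_id, counter, cursor, cfg, rng):
    gid = f"{species_id}_g{counter:04d}"
    seq = _random_protein(rng, cfg.protein_length)
    span = 3 * len(seq) + int(rng.integers(60, 400))
    start = cursor + _next_gap(rng, cfg.background_gap_bp)
    gene = GeneModel(gene_id=gid, scaffold=scaffold, start=start, end=start + span,
                     strand="+" if rng.random() < 0.5 else "-", protein_id=gid)
    genes.append(gene)
    genome.proteins[gid] = seq
    if rng.random() < 0.7:
        n_dom = int(rng.integers(1, 3))
        accs = rng.choice(len(NEUTRAL_POOL), size=n_dom, replace=False)
        genome.domains[gid] = [
            DomainHit(protein_id=gid, pfam_acc=NEUTRAL_POOL[i],
                      ali_start=1, ali_end=min(50, len(seq)),
                      evalue=float(f"1e-{int(rng.integers(10, 40))}"))
            for i in sorted(accs)
        ]
    return counter + 1, gene.end


def _emit_cluster(genome, genes, scaffold, species_id, counter, cursor, proto, cfg, rng, truth):
    member_ids: list[str] = []
    backbone_gid = ""
    tailoring_gids: list[str] = []
    first = True
    for k in proto.order:
        gid = f"{species_id}_g{counter:04d}"
        counter += 1
        seq = mutate_protein(proto.proteins[k], per_copy_identity(cfg.target_identity), rng)
        span = 3 * len(seq) + int(rng.integers(60, 400))
        gap = _next_gap(rng, cfg.flank_gap_bp if first else cfg.intra_cluster_gap_bp)
        first = False
        start = cursor + gap
        gene = GeneModel(gene_id=gid, scaffold=scaffold, start=start, end=start + span,
                         strand="+" if rng.random() < 0.5 else "-", protein_id=gid)
        genes.append(gene)
        cursor = gene.end
        genome.proteins[gid] = seq
        genome.domains[gid] = [
            DomainHit(protein_id=gid, pfam_acc=acc, ali_start=1,
                      ali_end=min(60, len(seq)),
                      evalue=float(f"1e-{int(rng.integers(15, 60))}"))
            for acc in proto.domains[k]
        ]
        member_ids.append(gid)
        if k == 0:
            backbone_gid = gid
        else:
            tailoring_gids.append(gid)
    # trailing flank so the next background gene is unreachable
    cursor = cursor + _next_gap(rng, cfg.flank_gap_bp)
    truth.clusters.append(
        PlantedCluster(
            species_id=species_id, family_label=proto.family_label,
            scaffold=scaffold, gene_ids=tuple(member_ids),
            backbone_gene_id=backbone_gid, backbone_class=proto.backbone_class,
            tailoring_gene_ids=tuple(tailoring_gids),
        )
    )
    return counter, cursor
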