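"""SMURF-style prediction of secondary-metabolite gene clusters.

Backbone genes are identified from the multi-domain PFAM composition of
each gene using an ordered rule table covering seven classes (PKS,
PKS-like, NRPS, NRPS-like, hybrid PKS-NRPS, DMATS prenyltransferase,
terpene cyclase).  Clusters are grown around each backbone seed along
the scaffold; extension stops at intergenic gaps above 3 kb or after a
run of more than six consecutive genes without an SM-specific PFAM
domain, and borders are trimmed back to the outermost gene with SM
evidence.  Touching extensions merge into a single cluster.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import AnnotatedGenome, GeneModel, intergenic_gap

BACKBONE_CLASSES = ("PKS", "PKS-like", "NRPS", "NRPS-like", "HYBRID", "DMATS", "TC")


@dataclass(frozen=True)
class BackboneRule:
    cls: str
    clauses: tuple[tuple[frozenset[str], int], ...]
    other_than: frozenset[str] | None = None

    def matches(self, accs: frozenset[str]) -> bool:
        for domains, k in self.clauses:
            if len(accs & domains) < k:
                return False
        if self.other_than is not None and not (accs - self.other_than):
            return False
        return True


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("smgc.data") / name)


def load_backbone_rules(
    path: str | Path | None = None, nrps_like_variant: str = "legend"
) -> list[BackboneRule]:
    """Load the ordered rule table; ``nrps_like_variant`` is legend|loose."""
    raw = yaml.safe_load(Path(path or _data_path("backbone_rules.yaml")).read_text())
    by_name: dict[str, BackboneRule] = {}
    for entry in raw["classes"]:
        if entry.get("variant") and entry["variant"] != nrps_like_variant:
            continue
        clauses = tuple(
            (frozenset(c["domains"]), int(c["min"])) for c in entry["clauses"]
        )
        other = entry.get("other_than")
        by_name[entry["name"]] = BackboneRule(
            cls=entry["name"],
            clauses=clauses,
            other_than=frozenset(other) if other else None,
        )
    missing = [c for c in raw["order"] if c not in by_name]
    if missing:
        raise ValueError(f"rule table lacks classes: {missing}")
    return [by_name[c] for c in raw["order"]]


def load_sm_pfams(path: str | Path | None = None) -> frozenset[str]:
    accs = []
    for line in Path(path or _data_path("sm_pfams.txt")).read_text().splitlines():
        acc = line.split("#", 1)[0].strip()
        if acc:
            accs.append(acc)
    return frozenset(accs)


@dataclass
class PredictorConfig:
    """Parameters of the cluster predictor.

    Defaults: at most 3 kb between consecutive cluster genes, at most 6
    consecutive genes without SM-specific domains inside a cluster.
    """

    max_intergenic_bp: int = 3000
    max_non_sm_genes: int = 6
    domain_evalue_cutoff: float = 1e-5
    nrps_like_variant: str = "legend"
    rules_path: str | Path | None = None
    sm_pfams_path: str | Path | None = None
    rules: list[BackboneRule] = field(default_factory=list)
    sm_pfams: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.rules:
            self.rules = load_backbone_rules(self.rules_path, self.nrps_like_variant)
        if not self.sm_pfams:
            self.sm_pfams = load_sm_pfams(self.sm_pfams_path)


@dataclass(frozen=True)
class BackboneCall:
    gene_id: str
    cls: str
    matched_domains: tuple[str, ...]


@dataclass
class SMGC:
    """A predicted secondary-metabolite gene cluster."""

    cluster_id: str
    species_id: str
    scaffold: str
    gene_ids: tuple[str, ...]
    backbones: tuple[BackboneCall, ...]
    tailoring_gene_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def backbone_gene_ids(self) -> tuple[str, ...]:
        return tuple(b.gene_id for b in self.backbones)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def classify_backbone(
    accs: frozenset[str] | set[str], rules: list[BackboneRule]
) -> str | None:
    """Return the first matching backbone class, or None."""
    accs = frozenset(accs)
    for rule in rules:
        if rule.matches(accs):
            return rule.cls
    return None


def _gene_accs(genome: AnnotatedGenome, gene: GeneModel, cutoff: float) -> frozenset[str]:
    return frozenset(
        h.pfam_acc for h in genome.domains_of(gene) if h.evalue <= cutoff
    )


def predict_clusters(genome: AnnotatedGenome, config: PredictorConfig | None = None) -> list[SMGC]:
    """Predict all clusters of one genome.

    Consecutive genes with SM evidence (a backbone composition or an
    SM-specific PFAM) are chained when every intergenic gap between
    them is within the limit and at most ``max_non_sm_genes`` genes
    without SM evidence lie between them.  Each chain containing at
    least one backbone becomes one cluster spanning its outermost SM
    genes, so extensions of nearby backbones merge and borders always
    carry SM evidence.
    """
    config = config or PredictorConfig()
    clusters: list[SMGC] = []
    counter = 0
    for scaffold in sorted(genome.genes):
        genes = genome.genes[scaffold]
        accs = [_gene_accs(genome, g, config.domain_evalue_cutoff) for g in genes]
        backbone_cls = [classify_backbone(a, config.rules) for a in accs]
        is_sm = [
            backbone_cls[i] is not None or bool(accs[i] & config.sm_pfams)
            for i in range(len(genes))
        ]
        sm_idx = [i for i, flag in enumerate(is_sm) if flag]
        for lo, hi in _chain_sm_genes(genes, sm_idx, config):
            if not any(backbone_cls[i] is not None for i in range(lo, hi + 1)):
                continue
            counter += 1
            members = genes[lo : hi + 1]
            calls = tuple(
                BackboneCall(
                    gene_id=genes[i].gene_id,
                    cls=backbone_cls[i],
                    matched_domains=tuple(sorted(accs[i])),
                )
                for i in range(lo, hi + 1)
                if backbone_cls[i] is not None
            )
            tailoring = tuple(
                genes[i].gene_id
                for i in range(lo, hi + 1)
                if backbone_cls[i] is None and accs[i] & config.sm_pfams
            )
            clusters.append(
                SMGC(
                    cluster_id=f"{genome.species_id}|{scaffold}|c{counter:03d}",
                    species_id=genome.species_id,
                    scaffold=scaffold,
                    gene_ids=tuple(g.gene_id for g in members),
                    backbones=calls,
                    tailoring_gene_ids=tailoring,
                    start=members[0].start,
                    end=members[-1].end,
                )
            )
    return clusters


def _chain_sm_genes(
    genes: list[GeneModel], sm_idx: list[int], config: PredictorConfig
) -> list[tuple[int, int]]:
    """Maximal runs of SM-evidence genes linked under the gap and run rules.

    Two consecutive SM genes link when every intergenic gap between
    them is <= max_intergenic_bp and at most max_non_sm_genes genes
    without SM evidence separate them.  Returned (lo, hi) index spans
    start and end on SM genes.
    """
    spans: list[tuple[int, int]] = []
    for i in sm_idx:
        if spans:
            prev_hi = spans[-1][1]
            linked = (i - prev_hi - 1) <= config.max_non_sm_genes and all(
                intergenic_gap(genes[j], genes[j + 1]) <= config.max_intergenic_bp
                for j in range(prev_hi, i)
            )
            if linked:
                spans[-1] = (spans[-1][0], i)
                continue
        spans.append((i, i))
    return spans


def backbone_census(clusters: list[SMGC]) -> pd.DataFrame:
    """Species x backbone-class count matrix over all backbone genes."""
    species = sorted({c.species_id for c in clusters})
    census = pd.DataFrame(0, index=species, columns=list(BACKBONE_CLASSES))
    for c in clusters:
        for b in c.backbones:
            census.loc[c.species_id, b.cls] += 1
    census.index.name = "species"
    return census
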