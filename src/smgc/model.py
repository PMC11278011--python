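"""Core domain types for annotated genomes.

Coordinates follow the GFF3 convention: 1-based, inclusive on both ends.
The intergenic distance between two consecutive genes ``g_i`` and
``g_{i+1}`` on a scaffold is ``start(g_{i+1}) - end(g_i) - 1``, i.e. the
number of base pairs strictly between them.  Strand is recorded but plays
no role in cluster prediction or scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PFAM_ACC_RE = re.compile(r"^PF\d{5}$")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene located on a scaffold."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A PFAM domain match on a protein."""

    protein_id: str
    pfam_acc: str
    ali_start: int
    ali_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"domain hit {self.pfam_acc} on {self.protein_id}: "
                f"ali_start {self.ali_start} > ali_end {self.ali_end}"
            )
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


def intergenic_gap(left: GeneModel, right: GeneModel) -> int:
    """Base pairs strictly between two genes (``right`` downstream of ``left``)."""
    return right.start - left.end - 1


@dataclass
class AnnotatedGenome:
    """Genes, PFAM domain hits and protein sequences of one genome.

    ``genes`` maps scaffold -> genes sorted by start coordinate;
    ``domains`` maps protein_id -> domain hits; ``proteins`` maps
    protein_id -> amino-acid sequence.
    """

    species_id: str
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)
    domains: dict[str, list[DomainHit]] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "AnnotatedGenome":
        seen: set[str] = set()
        for scaffold, genes in self.genes.items():
            starts = [g.start for g in genes]
            if starts != sorted(starts):
                raise ValueError(
                    f"{self.species_id}/{scaffold}: genes not sorted by start"
                )
            for g in genes:
                if g.gene_id in seen:
                    raise ValueError(
                        f"{self.species_id}: duplicate gene id {g.gene_id}"
                    )
                seen.add(g.gene_id)
                if g.protein_id not in self.proteins:
                    raise ValueError(
                        f"{self.species_id}: gene {g.gene_id} has no protein "
                        f"sequence for {g.protein_id}"
                    )
        for pid in self.domains:
            if pid not in self.proteins:
                raise ValueError(
                    f"{self.species_id}: domain hits reference unknown protein {pid}"
                )
        return self

    def all_genes(self) -> list[GeneModel]:
        """All genes, scaffolds in sorted order, genes by start within each."""
        out: list[GeneModel] = []
        for scaffold in sorted(self.genes):
            out.extend(self.genes[scaffold])
        return out

    def domains_of(self, gene: GeneModel) -> list[DomainHit]:
        return self.domains.get(gene.protein_id, [])

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())
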