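"""Readers and writers for the on-disk formats of the pipeline.

Genomes are read from a GFF3 (gene features), a protein FASTA and a
five-column domain TSV (``protein_id  pfam_acc  ali_start  ali_end
evalue``).  All tabular outputs are plain TSV with deterministic,
sorted row order so runs are byte-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import PFAM_ACC_RE, AnnotatedGenome, DomainHit, GeneModel

log = logging.getLogger(__name__)

DOMAIN_COLUMNS = ["protein_id", "pfam_acc", "ali_start", "ali_end", "evalue"]


def read_genome(
    gff_path: str | Path,
    protein_fasta_path: str | Path,
    domain_table_path: str | Path,
    species_id: str | None = None,
) -> AnnotatedGenome:
    """Load one genome from GFF3 + protein FASTA + domain TSV.

    Gene features must carry an ``ID`` attribute; a ``protein_id``
    attribute links the gene to its FASTA record (defaults to the gene
    ID).  Proteins not referenced by any gene are dropped with a
    warning; a gene without a protein is a hard error.
    """
    gff_path = Path(gff_path)
    if species_id is None:
        species_id = gff_path.stem
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta_path), "fasta")}

    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for feat in db.features_of_type("gene"):
        protein_id = feat.attributes.get("protein_id", [feat.id])[0]
        gene = GeneModel(
            gene_id=feat.id,
            scaffold=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in {"+", "-"} else "+",
            protein_id=protein_id,
        )
        genes_by_scaffold.setdefault(gene.scaffold, []).append(gene)
    for scaffold in genes_by_scaffold:
        genes_by_scaffold[scaffold].sort(key=lambda g: (g.start, g.gene_id))

    referenced = {g.protein_id for gs in genes_by_scaffold.values() for g in gs}
    for gs in genes_by_scaffold.values():
        for g in gs:
            if g.protein_id not in proteins:
                raise ValueError(
                    f"{species_id}: gene {g.gene_id} has no protein sequence "
                    f"for {g.protein_id}"
                )
    orphans = set(proteins) - referenced
    if orphans:
        log.warning(
            "%s: dropping %d proteins not referenced by any gene", species_id, len(orphans)
        )
        proteins = {k: v for k, v in proteins.items() if k in referenced}

    domains = read_domain_table(domain_table_path, known_proteins=set(proteins))
    return AnnotatedGenome(
        species_id=species_id,
        genes=genes_by_scaffold,
        domains=domains,
        proteins=proteins,
    ).validate()


def read_domain_table(
    path: str | Path, known_proteins: set[str] | None = None
) -> dict[str, list[DomainHit]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain table {path} lacks columns: {sorted(missing)}")
    domains: dict[str, list[DomainHit]] = {}
    for row in df.itertuples(index=False):
        if known_proteins is not None and row.protein_id not in known_proteins:
            raise ValueError(
                f"domain table references absent protein {row.protein_id}"
            )
        if not PFAM_ACC_RE.match(str(row.pfam_acc)):
            log.warning("unusual PFAM accession %r kept as-is", row.pfam_acc)
        hit = DomainHit(
            protein_id=row.protein_id,
            pfam_acc=str(row.pfam_acc),
            ali_start=int(row.ali_start),
            ali_end=int(row.ali_end),
            evalue=float(row.evalue),
        )
        domains.setdefault(hit.protein_id, []).append(hit)
    return domains


# ---------------------------------------------------------------------------
# genome writers (used by the simulator; emit exactly what read_genome reads)

def write_genome(genome: AnnotatedGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write GFF3 + protein FASTA + domain TSV for one genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = genome.species_id
    gff = out_dir / f"{sid}.gff3"
    fasta = out_dir / f"{sid}.proteins.fasta"
    dom = out_dir / f"{sid}.domains.tsv"

    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold in sorted(genome.genes):
            for g in genome.genes[scaffold]:
                fh.write(
                    f"{g.scaffold}\tsmgc\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};protein_id={g.protein_id}\n"
                )

    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(genome.proteins.items())
    ]
    SeqIO.write(records, str(fasta), "fasta")

    rows = [
        (h.protein_id, h.pfam_acc, h.ali_start, h.ali_end, h.evalue)
        for pid in sorted(genome.domains)
        for h in genome.domains[pid]
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(dom, sep="\t", index=False)
    return {"gff": gff, "fasta": fasta, "domains": dom}


# ---------------------------------------------------------------------------
# tabular result writers/readers

def write_cluster_table(clusters: Iterable, path: str | Path) -> None:
    """One gene per row: cluster_id, species, scaffold, gene_id, role."""
    rows = []
    for c in clusters:
        backbone_classes = {b.gene_id: b.cls for b in c.backbones}
        for gid in c.gene_ids:
            if gid in backbone_classes:
                role = f"backbone:{backbone_classes[gid]}"
            elif gid in c.tailoring_gene_ids:
                role = "tailoring"
            else:
                role = "other"
            rows.append((c.cluster_id, c.species_id, c.scaffold, gid, role))
    df = pd.DataFrame(
        rows, columns=["cluster_id", "species", "scaffold", "gene_id", "role"]
    ).sort_values(["cluster_id", "gene_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_score_table(scores: Iterable, path: str | Path) -> None:
    rows = [
        (s.cluster_a, s.cluster_b, s.score_tailoring, s.score_backbone, s.total)
        for s in scores
    ]
    df = pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "score_tailoring", "score_backbone", "total"],
    ).sort_values(["cluster_a", "cluster_b"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_family_table(families: Iterable, path: str | Path) -> None:
    rows = []
    for fam in families:
        label = ";".join(fam.compound_labels) if fam.compound_labels else ""
        for cid, sp in sorted(zip(fam.cluster_ids, fam.species_of_members)):
            rows.append((fam.family_id, cid, sp, fam.singleton, label))
    df = pd.DataFrame(
        rows,
        columns=["family_id", "cluster_id", "species", "singleton_flag", "compound_label"],
    ).sort_values(["family_id", "cluster_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_family_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_shared_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.sort_index(axis=0).sort_index(axis=1).to_csv(path, sep="\t")


def read_shared_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
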