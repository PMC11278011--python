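"""Genetic dereplication against characterized MIBiG-style clusters.

Reference clusters are read from GenBank records (CDS ``translation``
qualifiers only; no conceptual translation), filtered to the taxa of
interest.  A predicted cluster is linked to a reference when any of its
proteins aligns at more than 95% identity with sufficient query
coverage, and the compound label then propagates to the cluster's
whole family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .align import AlignParams, HitTable, align_pair
from .families import SMGCFamily
from .predict import SMGC

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MibigRecord:
    accession: str
    compound_name: str
    organism: str
    proteins: dict[str, str] = field(hash=False)


@dataclass
class DereplicationConfig:
    min_pident: float = 95.0  # strict: a hit must exceed this
    min_query_cov: float = 0.5
    taxon_filter: tuple[str, ...] = ("Aspergillus", "Penicillium")
    evalue_cutoff: float = 1e-10
    require_multi_gene: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_pident <= 100:
            raise ValueError("min_pident must be in (0, 100]")


def load_mibig(
    genbank_dir: str | Path, config: DereplicationConfig | None = None
) -> list[MibigRecord]:
    """Parse a directory of GenBank files into taxon-filtered records."""
    config = config or DereplicationConfig()
    records: list[MibigRecord] = []
    paths = sorted(Path(genbank_dir).glob("*.gbk")) + sorted(Path(genbank_dir).glob("*.gb"))
    if not paths:
        raise ValueError(f"no GenBank files found under {genbank_dir}")
    for path in paths:
        try:
            seqrecords = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:
            log.warning("skipping unparseable GenBank %s: %s", path.name, exc)
            continue
        for rec in seqrecords:
            organism = rec.annotations.get("organism", "")
            if not any(t in organism for t in config.taxon_filter):
                continue
            compound = rec.description.split(" biosynthetic")[0] or rec.id
            proteins: dict[str, str] = {}
            for i, feat in enumerate(rec.features):
                if feat.type != "CDS":
                    continue
                translation = feat.qualifiers.get("translation", [None])[0]
                pid = feat.qualifiers.get("protein_id", [f"{rec.id}_cds{i}"])[0]
                if not translation:
                    log.warning("%s: CDS %s lacks a translation, omitted", rec.id, pid)
                    continue
                proteins[f"{rec.id}|{pid}"] = translation
            if proteins:
                records.append(
                    MibigRecord(
                        accession=rec.id, compound_name=compound,
                        organism=organism, proteins=proteins,
                    )
                )
    if not records:
        raise ValueError("no records left after taxon filtering")
    return records


def hits_to_records(
    records: list[MibigRecord],
    cluster_proteins: dict[str, str],
    config: DereplicationConfig | None = None,
) -> HitTable:
    """Align every reference protein against every cluster protein."""
    config = config or DereplicationConfig()
    params = AlignParams(evalue_cutoff=config.evalue_cutoff)
    table = HitTable(config.evalue_cutoff)
    for rec in records:
        for qid, qseq in sorted(rec.proteins.items()):
            for sid, sseq in sorted(cluster_proteins.items()):
                hit = align_pair(qseq, sseq, params, query_id=qid, subject_id=sid)
                if hit is not None:
                    table.add(hit)
    return table


def dereplicate_families(
    families: list[SMGCFamily],
    clusters: list[SMGC],
    records: list[MibigRecord],
    hits: HitTable,
    gene_to_protein: dict[str, str],
    config: DereplicationConfig | None = None,
) -> list[SMGCFamily]:
    """Attach compound labels to families; labels are family-closed.

    A family is labelled by a record when any member cluster protein is
    hit by any of the record's proteins above the identity and coverage
    floors (or, in multi-gene mode, at least two distinct cluster
    proteins).  Multiple labels are concatenated sorted by accession.
    """
    config = config or DereplicationConfig()
    protein_to_cluster: dict[str, str] = {}
    for c in clusters:
        for gid in c.gene_ids:
            protein_to_cluster[gene_to_protein[gid]] = c.cluster_id
    family_of_cluster = {
        cid: fam.family_id for fam in families for cid in fam.cluster_ids
    }
    # family_id -> accession -> supporting cluster proteins
    support: dict[str, dict[str, set[str]]] = {}
    by_accession = {r.accession: r for r in records}
    for rec in records:
        for hit in hits:
            if not hit.query_id.startswith(f"{rec.accession}|"):
                continue
            if hit.pident <= config.min_pident or hit.query_cov < config.min_query_cov:
                continue
            cid = protein_to_cluster.get(hit.subject_id)
            if cid is None or cid not in family_of_cluster:
                continue
            fam_id = family_of_cluster[cid]
            support.setdefault(fam_id, {}).setdefault(rec.accession, set()).add(hit.subject_id)

    labelled = []
    for fam in families:
        accs = []
        for acc, proteins in sorted(support.get(fam.family_id, {}).items()):
            if config.require_multi_gene and len(proteins) < 2:
                continue
            accs.append(acc)
        labels = tuple(
            f"{acc}:{by_accession[acc].compound_name}" for acc in accs
        )
        labelled.append(replace(fam, compound_labels=labels))
    return labelled


def compound_presence_matrix(families: list[SMGCFamily]):
    """Compound-label x species presence/absence table."""
    import pandas as pd

    species = sorted({s for f in families for s in f.species_set})
    labels = sorted({lab for f in families for lab in f.compound_labels})
    mat = pd.DataFrame(0, index=labels, columns=species)
    for fam in families:
        for lab in fam.compound_labels:
            for sp in fam.species_set:
                mat.loc[lab, sp] = 1
    mat.index.name = "compound"
    return mat
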