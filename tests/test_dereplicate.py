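"""Genetic dereplication against synthetic GenBank reference clusters.

All GenBank fixtures are synthetic records written at test time; no
real repository data is bundled.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from smgc.dereplicate import (
    DereplicationConfig, dereplicate_families, hits_to_records, load_mibig,
)
from smgc.families import SMGCFamily
from smgc.predict import BackboneCall, SMGC

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def _write_gbk(path, accession, organism, proteins, compound="testomycin"):
    """Write one synthetic MIBiG-style GenBank record."""
    n_cds = len(proteins)
    rec = SeqRecord(
        Seq("ATGC" * 30 * max(1, n_cds)),
        id=accession, name=accession,
        description=f"{compound} biosynthetic gene cluster",
        annotations={"organism": organism, "molecule_type": "DNA"},
    )
    for i, (pid, seq) in enumerate(sorted(proteins.items())):
        qualifiers = {"protein_id": [pid]}
        if seq is not None:
            qualifiers["translation"] = [seq]
        rec.features.append(
            SeqFeature(FeatureLocation(i * 100, i * 100 + 90), type="CDS",
                       qualifiers=qualifiers)
        )
    SeqIO.write([rec], str(path), "genbank")


def _random_seq(rng, n=100):
    return "".join(rng.choice(AAS, size=n))


def _mutated(seq, n_subs, rng):
    """Substitute n interior positions so the full-length alignment is optimal."""
    chars = list(seq)
    positions = rng.choice(np.arange(10, len(seq) - 10), size=n_subs, replace=False)
    for pos in positions:
        chars[pos] = [c for c in AAS if c != chars[pos]][0]
    return "".join(chars)


def test_load_mibig_parses_and_filters(tmp_path):
    rng = np.random.default_rng(0)
    _write_gbk(tmp_path / "a.gbk", "BGC900001", "Aspergillus terreus",
               {f"p{i}": _random_seq(rng) for i in range(3)})
    _write_gbk(tmp_path / "b.gbk", "BGC900002", "Fusarium sp.",
               {"q0": _random_seq(rng)})
    records = load_mibig(tmp_path)
    assert len(records) == 1
    assert records[0].accession == "BGC900001"
    assert len(records[0].proteins) == 3
    assert records[0].compound_name == "testomycin"


def test_cds_without_translation_is_omitted(tmp_path, caplog):
    rng = np.random.default_rng(1)
    _write_gbk(tmp_path / "a.gbk", "BGC900003", "Penicillium rubens",
               {"p0": _random_seq(rng), "p1": None})
    (record,) = load_mibig(tmp_path)
    assert len(record.proteins) == 1


def test_nothing_after_taxon_filter_is_an_error(tmp_path):
    rng = np.random.default_rng(2)
    _write_gbk(tmp_path / "a.gbk", "BGC900004", "Fusarium oxysporum",
               {"p0": _random_seq(rng)})
    with pytest.raises(ValueError, match="taxon"):
        load_mibig(tmp_path)


def test_unparseable_file_is_skipped(tmp_path):
    rng = np.random.default_rng(3)
    (tmp_path / "broken.gbk").write_text("this is not genbank\n")
    _write_gbk(tmp_path / "ok.gbk", "BGC900005", "Aspergillus niger",
               {"p0": _random_seq(rng)})
    records = load_mibig(tmp_path)
    assert [r.accession for r in records] == ["BGC900005"]


def _one_cluster_family(cluster_seq, rng):
    """One family of two clusters; only cluster c1 carries cluster_seq."""
    c1 = SMGC("c1", "spA", "sc1", ("g1",),
              (BackboneCall("g1", "PKS", ("PF00109",)),), (), 1, 100)
    c2 = SMGC("c2", "spB", "sc1", ("g2",),
              (BackboneCall("g2", "PKS", ("PF00109",)),), (), 1, 100)
    fam = SMGCFamily("F1", ("c1", "c2"), ("spA", "spB"))
    g2p = {"g1": "prot1", "g2": "prot2"}
    proteins = {"prot1": cluster_seq, "prot2": _random_seq(rng)}
    return [c1, c2], [fam], g2p, proteins


@pytest.mark.parametrize("n_subs,expect_label", [(4, True), (6, False)])
def test_identity_threshold_is_strictly_over_95(tmp_path, n_subs, expect_label):
    """96% identity labels the family; 94% does not (cutoff: >95)."""
    rng = np.random.default_rng(10 + n_subs)
    cluster_seq = _random_seq(rng, 100)
    query = _mutated(cluster_seq, n_subs, rng) + _random_seq(rng, 66)
    _write_gbk(tmp_path / "ref.gbk", "BGC900010", "Aspergillus terreus",
               {"bb": query})
    records = load_mibig(tmp_path)
    clusters, fams, g2p, proteins = _one_cluster_family(cluster_seq, rng)
    hits = hits_to_records(records, proteins)
    hit = hits.get("BGC900010|bb", "prot1")
    assert hit is not None
    assert hit.pident == pytest.approx(100 - n_subs, abs=0.5)
    assert 0.55 < hit.query_cov < 0.65
    labelled = dereplicate_families(fams, clusters, records, hits, g2p)
    assert bool(labelled[0].compound_labels) is expect_label
    if expect_label:
        # label propagation is family-closed: c2 never matched, same label set
        assert labelled[0].cluster_ids == ("c1", "c2")


def test_perfect_match_labels_whole_family(tmp_path):
    rng = np.random.default_rng(20)
    cluster_seq = _random_seq(rng, 120)
    _write_gbk(tmp_path / "ref.gbk", "BGC900011", "Aspergillus terreus",
               {"bb": cluster_seq}, compound="terreusin")
    records = load_mibig(tmp_path)
    clusters, fams, g2p, proteins = _one_cluster_family(cluster_seq, rng)
    hits = hits_to_records(records, proteins)
    labelled = dereplicate_families(fams, clusters, records, hits, g2p)
    assert labelled[0].compound_labels == ("BGC900011:terreusin",)


def test_two_records_give_two_sorted_labels(tmp_path):
    rng = np.random.default_rng(21)
    seq_a, seq_b = _random_seq(rng, 100), _random_seq(rng, 100)
    _write_gbk(tmp_path / "r2.gbk", "BGC900022", "Aspergillus terreus",
               {"x": seq_b}, compound="beta")
    _write_gbk(tmp_path / "r1.gbk", "BGC900021", "Penicillium rubens",
               {"y": seq_a}, compound="alpha")
    records = load_mibig(tmp_path)
    c1 = SMGC("c1", "spA", "sc1", ("g1",),
              (BackboneCall("g1", "PKS", ("PF00109",)),), (), 1, 100)
    c2 = SMGC("c2", "spB", "sc1", ("g2",),
              (BackboneCall("g2", "PKS", ("PF00109",)),), (), 1, 100)
    fam = SMGCFamily("F1", ("c1", "c2"), ("spA", "spB"))
    g2p = {"g1": "prot1", "g2": "prot2"}
    proteins = {"prot1": seq_a, "prot2": seq_b}
    hits = hits_to_records(records, proteins)
    labelled = dereplicate_families([fam], [c1, c2], records, hits, g2p)
    assert labelled[0].compound_labels == ("BGC900021:alpha", "BGC900022:beta")


def test_lowering_min_pident_never_removes_labels(tmp_path):
    rng = np.random.default_rng(22)
    cluster_seq = _random_seq(rng, 100)
    query = _mutated(cluster_seq, 3, rng)
    _write_gbk(tmp_path / "ref.gbk", "BGC900030", "Aspergillus terreus",
               {"bb": query})
    records = load_mibig(tmp_path)
    clusters, fams, g2p, proteins = _one_cluster_family(cluster_seq, rng)
    hits = hits_to_records(records, proteins)
    strict = dereplicate_families(fams, clusters, records, hits, g2p,
                                  DereplicationConfig(min_pident=96.9))
    loose = dereplicate_families(fams, clusters, records, hits, g2p,
                                 DereplicationConfig(min_pident=90.0))
    assert set(strict[0].compound_labels) <= set(loose[0].compound_labels)


def test_invalid_identity_floor_rejected():
    with pytest.raises(ValueError):
        DereplicationConfig(min_pident=0.0)
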