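"""Backbone classification and cluster boundary rules."""

from __future__ import annotations

import pytest

from smgc.model import intergenic_gap
from smgc.predict import (
    PredictorConfig, backbone_census, classify_backbone, load_backbone_rules,
    predict_clusters,
)

from conftest import NEUTRAL, NRPS, P450, PKS, make_genome

CFG = PredictorConfig()


# -- classification -----------------------------------------------------------

@pytest.mark.parametrize(
    "accs,expected",
    [
        ({"PF00109", "PF00698", "PF00550"}, "PKS"),
        ({"PF02801", "PF00698"}, "PKS"),
        ({"PF00668", "PF00501", "PF00550"}, "NRPS"),
        # PKS and NRPS core domains together resolve to HYBRID first
        ({"PF00109", "PF00698", "PF00668", "PF00501"}, "HYBRID"),
        # two PKS-specific domains plus another domain
        ({"PF00109", "PF02801", "PF00067"}, "PKS-like"),
        # condensation + adenylation + thioesterase, no carrier: NRPS-like
        ({"PF00668", "PF00501", "PF00975"}, "NRPS-like"),
        ({"PF11991"}, "DMATS"),
        ({"PF06330"}, "TC"),
        (set(), None),
        ({"PF90001", "PF00067"}, None),  # tailoring domains alone are no backbone
    ],
)
def test_classify_backbone_rule_table(accs, expected):
    assert classify_backbone(accs, CFG.rules) == expected


def test_two_pks_specific_without_other_domain_is_not_pks_like():
    assert classify_backbone({"PF00109", "PF02801"}, CFG.rules) is None


def test_loose_nrps_like_variant_drops_condensation_requirement():
    loose = load_backbone_rules(nrps_like_variant="loose")
    assert classify_backbone({"PF00501", "PF00975"}, loose) == "NRPS-like"
    assert classify_backbone({"PF00501", "PF00975"}, CFG.rules) is None


# -- cluster extension --------------------------------------------------------

def _gene_row(gid, start, length, accs):
    return (gid, start, start + length - 1, accs)


def test_three_gene_cluster_with_small_gaps():
    genome = make_genome("t1", [
        _gene_row("g1", 1_000, 900, P450),
        _gene_row("g2", 2_900, 1_500, PKS),      # 1 kb gap to g1
        _gene_row("g3", 5_400, 900, P450),       # 1 kb gap to g2
    ])
    clusters = predict_clusters(genome, CFG)
    assert len(clusters) == 1
    assert clusters[0].gene_ids == ("g1", "g2", "g3")
    assert clusters[0].tailoring_gene_ids == ("g1", "g3")


def test_gap_above_3kb_excludes_tailoring_gene():
    genome = make_genome("t2", [
        _gene_row("bb", 1_000, 1_500, PKS),
        _gene_row("tg", 6_001, 900, P450),       # 3.5 kb gap
    ])
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb",)


def test_gap_exactly_3kb_is_still_inside():
    genome = make_genome("t3", [
        _gene_row("bb", 1_000, 1_500, PKS),      # ends 2499
        _gene_row("tg", 5_500, 900, P450),       # gap exactly 3000
    ])
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb", "tg")


def test_seven_sm_free_genes_stop_extension():
    genes = [_gene_row("bb", 1_000, 1_000, PKS)]
    pos = 2_500
    for i in range(7):
        genes.append(_gene_row(f"n{i}", pos, 800, NEUTRAL))
        pos += 1_000
    genes.append(_gene_row("tg", pos, 800, P450))
    genome = make_genome("t4", genes)
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb",)


def test_six_sm_free_genes_are_bridged_and_kept_inside():
    genes = [_gene_row("bb", 1_000, 1_000, PKS)]
    pos = 2_500
    for i in range(6):
        genes.append(_gene_row(f"n{i}", pos, 800, NEUTRAL))
        pos += 1_000
    genes.append(_gene_row("tg", pos, 800, P450))
    genome = make_genome("t5", genes)
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb",) + tuple(f"n{i}" for i in range(6)) + ("tg",)
    assert cluster.tailoring_gene_ids == ("tg",)


def test_borders_are_trimmed_to_sm_evidence():
    genome = make_genome("t6", [
        _gene_row("n0", 1_000, 800, NEUTRAL),
        _gene_row("bb", 2_200, 1_000, PKS),
        _gene_row("n1", 3_700, 800, NEUTRAL),
    ])
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb",)


def test_nearby_backbones_merge_into_one_cluster():
    genome = make_genome("t7", [
        _gene_row("bb1", 1_000, 1_500, PKS),
        _gene_row("mid", 3_000, 800, P450),
        _gene_row("bb2", 4_300, 1_500, NRPS),
    ])
    (cluster,) = predict_clusters(genome, CFG)
    assert cluster.gene_ids == ("bb1", "mid", "bb2")
    assert {b.cls for b in cluster.backbones} == {"PKS", "NRPS"}


def test_distant_backbones_stay_separate():
    genome = make_genome("t8", [
        _gene_row("bb1", 1_000, 1_500, PKS),
        _gene_row("bb2", 10_000, 1_500, NRPS),
    ])
    clusters = predict_clusters(genome, CFG)
    assert [c.gene_ids for c in clusters] == [("bb1",), ("bb2",)]


def test_no_backbone_no_clusters():
    genome = make_genome("t9", [
        _gene_row("tg1", 1_000, 800, P450),
        _gene_row("tg2", 2_500, 800, P450),
    ])
    assert predict_clusters(genome, CFG) == []


def test_emitted_clusters_satisfy_internal_invariants(small_pangenome):
    genomes, _ = small_pangenome
    for genome in genomes:
        for c in predict_clusters(genome, CFG):
            genes = {g.gene_id: g for gs in genome.genes.values() for g in gs}
            members = [genes[g] for g in c.gene_ids]
            run = 0
            for left, right in zip(members, members[1:]):
                assert intergenic_gap(left, right) <= CFG.max_intergenic_bp
            for g in members:
                accs = frozenset(h.pfam_acc for h in genome.domains_of(g))
                if accs & CFG.sm_pfams or classify_backbone(accs, CFG.rules):
                    run = 0
                else:
                    run += 1
                    assert run <= CFG.max_non_sm_genes


def test_predictions_equal_truth_on_simulator_output(small_pangenome):
    genomes, truth = small_pangenome
    expected = truth.extent_map()
    predicted = {}
    for genome in genomes:
        for c in predict_clusters(genome, CFG):
            predicted[(c.species_id, frozenset(c.gene_ids))] = c
    assert set(predicted) == set(expected)
    for key, cluster in predicted.items():
        assert len(cluster.backbones) == 1
        assert cluster.backbones[0].cls == expected[key].backbone_class
        assert set(cluster.tailoring_gene_ids) == set(expected[key].tailoring_gene_ids)


def test_raising_gap_limit_never_shrinks_clusters(small_pangenome):
    genomes, _ = small_pangenome
    loose = PredictorConfig(max_intergenic_bp=8000)
    for genome in genomes:
        loose_clusters = predict_clusters(genome, loose)
        for c in predict_clusters(genome, CFG):
            covering = [
                lc for lc in loose_clusters
                if set(c.gene_ids) <= set(lc.gene_ids)
            ]
            assert covering, f"cluster {c.cluster_id} lost genes at looser gap limit"


def test_backbone_census_counts(small_pangenome):
    genomes, truth = small_pangenome
    clusters = [c for g in genomes for c in predict_clusters(g, CFG)]
    census = backbone_census(clusters)
    expected = truth.backbone_census()
    assert census.loc[expected.index, expected.columns].equals(expected)
    # row sums equal total backbone genes per species
    for sp in census.index:
        total = sum(len(c.backbones) for c in clusters if c.species_id == sp)
        assert census.loc[sp].sum() == total


def test_backbone_census_empty_input():
    census = backbone_census([])
    assert census.empty or (census.to_numpy() == 0).all()
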