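from __future__ import annotations

import numpy as np
import pytest

from smgc.model import AnnotatedGenome, DomainHit, GeneModel
from smgc.pipeline import run_pipeline
from smgc.simulate import SimConfig, generate_pangenome

PKS = ("PF00109", "PF02801", "PF00698", "PF00550")
NRPS = ("PF00668", "PF00501", "PF00550")
P450 = ("PF00067",)  # SM-specific tailoring domain
NEUTRAL = ("PF90001",)  # not SM-specific


def make_genome(species_id: str, genes: list[tuple], scaffold: str = "sc1") -> AnnotatedGenome:
    """Build a genome from (gene_id, start, end, pfam_accs) tuples.

    Proteins are deterministic dummies; domain hits get e-value 1e-30.
    """
    genome = AnnotatedGenome(species_id=species_id)
    genome.genes[scaffold] = []
    rng = np.random.default_rng(abs(hash(species_id)) % (2**31))
    for gid, start, end, accs in genes:
        genome.genes[scaffold].append(
            GeneModel(gene_id=gid, scaffold=scaffold, start=start, end=end,
                      strand="+", protein_id=gid)
        )
        genome.proteins[gid] = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60)
        )
        if accs:
            genome.domains[gid] = [
                DomainHit(protein_id=gid, pfam_acc=acc, ali_start=1, ali_end=40,
                          evalue=1e-30)
                for acc in accs
            ]
    return genome.validate()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # explicit presence design: one planted singleton family (fam000)
    return SimConfig(
        n_species=3,
        scaffolds_per_genome=1,
        genes_per_scaffold=12,
        n_planted_families=4,
        family_presence=[[0], [0, 1], [0, 1, 2], [1, 2]],
        target_identity=85.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def small_result(small_pangenome):
    genomes, _ = small_pangenome
    return run_pipeline(genomes)
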