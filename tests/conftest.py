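"""Shared fixtures: a hand-sized gene, the default simulation gene, a family."""

from __future__ import annotations

import pytest

from hacsplice.degron import find_degron
from hacsplice.gene_model import GeneModel, build_junction_queries
from hacsplice.synthetic import FamilySimConfig, default_gene, simulate_family


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Small gene with a hand-traceable reading frame.

    exon1 = ATGGCTG (7 nt, one carried nt), intron carries an in-frame TGA
    at intron sites 12-14, so the degron peptide is AVIT.
    """
    return GeneModel(
        gene_id="toy",
        utr5="TTTT",
        exon1="ATGGCTG",
        intron="CAGTTATCACTTGAGGGAAACCTTGGCCAATT",
        exon2="GGCCTTAAGGCCTTAAGGCC",
        utr3="CCCC",
    )


@pytest.fixture(scope="session")
def sim_gene() -> GeneModel:
    return default_gene()


@pytest.fixture(scope="session")
def sim_queries(sim_gene):
    deg = find_degron(sim_gene)
    return build_junction_queries(sim_gene, deg.stop1_intron_pos)


@pytest.fixture(scope="session")
def family_50():
    """50 simulated ortholog species with planted degron outcomes, seed-fixed."""
    cfg = FamilySimConfig(ancestor=default_gene(), n_species=50, seed=7)
    species, truth = simulate_family(cfg)
    return species, truth
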