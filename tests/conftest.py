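"""Shared fixtures: small simulated populations and toy gene models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recmap.annotate import InMemoryReference
from recmap.genotypes import GenotypeMatrix
from recmap.simulate import (
    SequencePanelConfig,
    SimulationConfig,
    gene_drop,
    simulate_gene_model,
    simulate_pedigree,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_founders=200,
        n_generations=5,
        n_markers=120,
        chrom_length_bp=2_000_000,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    ped = simulate_pedigree(small_config)
    geno = gene_drop(ped, small_config)
    return ped, geno


@pytest.fixture(scope="session")
def study():
    """A complete small study: genotypes, phenotypes, panel, gene, truth."""
    config = SimulationConfig(
        n_founders=350,
        n_generations=6,
        n_markers=250,
        chrom_length_bp=2_000_000,
        seed=3,
    )
    panel_config = SequencePanelConfig(seed=3, n_region_variants=120)
    return simulate_study(config, panel_config)


def make_genotype_matrix(calls, chrom="19", positions=None, haplotypes=None, ids=None):
    """Hand-built GenotypeMatrix for toy examples."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    markers = pd.DataFrame(
        {
            "name": [f"M{j:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "C",
        }
    )
    if ids is None:
        ids = np.array([f"I{i:03d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids=np.asarray(ids, dtype=object), calls=calls,
                          markers=markers, haplotypes=haplotypes)


@pytest.fixture()
def toy_gene():
    """183-codon gene (stop included) with TGC at codon 161 and CAG at 66."""
    rng = np.random.default_rng(42)
    gm, cds, patches = simulate_gene_model(
        chrom="19",
        cds_start_bp=10_001,
        rng=rng,
        special_codons={66: "CAG", 161: "TGC"},
    )
    length = max(e for _, e in gm.exons) + 500
    seq = list("".join(np.random.default_rng(7).choice(list("ACGT"), size=length)))
    for s, e, sub in patches:
        seq[s - 1 : e] = list(sub)
    reference = InMemoryReference({"19": "".join(seq)})
    return gm, cds, reference


@pytest.fixture()
def long_gene():
    """260-codon gene with CCA at codon 236 and TTC at codon 250."""
    rng = np.random.default_rng(11)
    gm, cds, patches = simulate_gene_model(
        chrom="19",
        cds_start_bp=5_001,
        rng=rng,
        gene="ACADVL",
        n_codons=260,
        special_codons={236: "CCA", 250: "TTC"},
    )
    length = max(e for _, e in gm.exons) + 500
    seq = list("".join(np.random.default_rng(8).choice(list("ACGT"), size=length)))
    for s, e, sub in patches:
        seq[s - 1 : e] = list(sub)
    reference = InMemoryReference({"19": "".join(seq)})
    return gm, cds, reference
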