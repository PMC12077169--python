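import numpy as np
import pandas as pd
import pytest

from firmqtl.simpop import (
    SimConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def discovery_config() -> SimConfig:
    """Default study conditions at the discovery-population size (n=85)."""
    return SimConfig(n_individuals=85, seed=11)


@pytest.fixture(scope="session")
def discovery_pop(discovery_config):
    """(G, pheno, truth) for the shared n=85 population."""
    G = simulate_genotypes(discovery_config)
    pheno, truth = simulate_phenotypes(discovery_config, G)
    return G, pheno, truth


@pytest.fixture(scope="session")
def discovery_counts(discovery_config, discovery_pop):
    G, _, _ = discovery_pop
    return simulate_expression(discovery_config, G)


@pytest.fixture(scope="session")
def clone_means(discovery_pop):
    """Per-individual phenotype means aligned with the genotype matrix
    (the design is balanced, so these equal the estimated marginal
    means)."""
    G, pheno, _ = discovery_pop
    return (pheno.groupby("individual")["value"].mean()
            .loc[G.individuals].to_numpy())


def noise_free_config(**overrides) -> SimConfig:
    """A deterministic single-observation design with no random variance."""
    base = dict(
        n_individuals=40, n_markers=3, major_locus_index=1,
        major_locus_maf=0.5, sigma2_G=0.0, sigma2_GY=0.0, sigma2_e=0.0,
        sigma2_Y=0.0, sigma2_LY=0.0, sigma2_LYB=0.0,
        location_effects=(0.0,), n_locations=1, n_years=1, n_blocks=1,
        n_harvests=1, n_genes=4, focal_gene_index=1, seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)
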