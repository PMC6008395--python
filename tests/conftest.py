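import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("det", derandomize=True)
hyp_settings.load_profile("det")

from mirnet_gsa.synthetic import SimulationConfig, simulate_genotypes, \
    simulate_annotation, simulate_target_networks


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured cohort: 200 animals, 1,250 markers."""
    return SimulationConfig(
        seed=7, n_individuals=200, n_chromosomes=5, markers_per_chrom=250,
        n_genes=60, n_mirnas=12, mean_targets_per_mirna=12.0,
        target_size_range=(5, 25),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Genotypes, annotation and networks for the small cohort."""
    geno = simulate_genotypes(small_config)
    genes, mirnas = simulate_annotation(small_config)
    networks = simulate_target_networks(mirnas["mirna_id"], genes["gene_id"],
                                        small_config)
    return {"config": small_config, "genotypes": geno, "genes": genes,
            "mirnas": mirnas, "networks": networks}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
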