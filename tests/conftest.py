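import numpy as np
import pytest

from geotax.simulate import SimConfig, simulate_collection


@pytest.fixture(scope="session")
def small_collection():
    """Two genera x three species, 40 kb genomes, 40 genes: fast shared bed."""
    config = SimConfig(
        n_genera=2,
        species_per_genus=3,
        genome_len_bp=40_000,
        n_genes=40,
        gene_len_aa=180,
        gc_target=62.0,
        p_s=0.02,
        p_g=0.12,
        gene_loss_prob=0.2,
        seed=7,
    )
    return simulate_collection(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
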