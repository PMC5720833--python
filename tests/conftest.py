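import pytest
from hypothesis import settings

from bsamap import (SimulationConfig, build_pools, generate_parental_pair,
                    simulate_cross)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A miniature cross: 2 chromosomes x 3 genes, ~4 kb of genome."""
    return SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=3,
        gene_length_range=(300, 450),
        intergenic_length_range=(120, 240),
        causal_gene="c2g02",
        causal_cds_length=399,
        causal_insertion_offset=200,
        mating_type_locus="c1g02",
        n_segregants=80,
        pool_sizes=(8, 8, 8, 8),
        per_clone_coverage=0.4,
        parent_coverage=8.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return generate_parental_pair(small_config)


@pytest.fixture(scope="session")
def small_cross(small_config, small_pair):
    segregants = simulate_cross(small_pair, small_config)
    pools = build_pools(segregants, small_config.pool_sizes, small_config.seed)
    return segregants, pools
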