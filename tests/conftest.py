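import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsamap import simdata

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    """Two 5 Mb chromosomes, 0.6 Morgan, 250 evenly spaced SNPs each."""
    return simdata.default_map(
        n_chromosomes=2,
        chromosome_length=5_000_000,
        genetic_length_morgans=0.6,
        snps_per_chromosome=250,
    )


@pytest.fixture(scope="session")
def causal(small_map):
    snps = small_map.snp_positions["Chr1"]
    return simdata.CausalLocusSpec(chromosome="Chr1", position=int(snps[snps.size // 2]))


@pytest.fixture(scope="session")
def population(small_map, causal):
    return simdata.simulate_f2_population(small_map, causal, n=300, seed=11)


@pytest.fixture(scope="session")
def depth_records(population):
    bulk = simdata.BulkSpec(bulk_size=30, mean_depth=30.0)
    return simdata.simulate_bulk_depths(population, bulk, seed=23)
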