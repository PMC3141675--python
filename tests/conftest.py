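import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eqtlscan import simdata

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully-featured simulation configuration."""
    return simdata.SimConfig(
        n_lines=80,
        n_markers=100,
        n_chromosomes=5,
        chrom_length_cM=100.0,
        n_intermating_generations=10,
        intermating_pop_size=100,
        n_probes=80,
        n_cis_effects=20,
        n_trans_effects=8,
        missing_genotype_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config, n_replicates=2)


@pytest.fixture(scope="session")
def tiny_map():
    return simdata.simulate_map(
        simdata.SimConfig(n_markers=20, n_chromosomes=2,
                          chrom_length_cM=100.0, seed=5)
    )


def two_class_expression(codes_at_marker, low=100.0, high=900.0,
                         noise=0.0, rng=None):
    """Expression split by a genotype column: high for B73 carriers."""
    e = np.where(codes_at_marker == 0, high, low).astype(float)
    if noise > 0:
        e = e + rng.normal(0, noise, size=e.size)
    return e
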