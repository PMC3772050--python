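import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dmrkit import (
    Genome,
    MethylomeSimConfig,
    MethylomeTable,
    plant_dmrs_uniform,
    simulate_features,
    simulate_methylome_pair,
)


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return Genome({"Chr1": "ACGTTCGAACAGTACTTTCCGGAA", "Chr2": "TTCGAATTACGT"})


@pytest.fixture(scope="session")
def sim_pair():
    """A 200-kb simulated methylome pair with 20 planted CG DMRs."""
    lengths = MethylomeSimConfig(genome_length=200_000).chrom_lengths
    planted = plant_dmrs_uniform(lengths, 20, 400, "CG", 0.4, seed=11)
    config = MethylomeSimConfig(genome_length=200_000, planted_dmrs=planted, seed=11)
    return simulate_methylome_pair(config)


@pytest.fixture(scope="session")
def sim_features(sim_pair):
    genome = sim_pair[0]
    return simulate_features(genome, n_genes=30, n_tes=15, seed=7)
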