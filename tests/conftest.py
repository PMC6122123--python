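import numpy as np
import pytest

from recinv import ChromosomeSpec, CrossConfig, TruthInversion, simulate_cross


@pytest.fixture(scope="session")
def small_genome():
    """Three 10 Mb chromosomes: enough structure without genome-scale cost."""
    return [ChromosomeSpec(f"chr{i + 1}", 10_000_000) for i in range(3)]


@pytest.fixture(scope="session")
def clean_cross(small_genome):
    """Error-free within-species cross of 200 offspring."""
    return simulate_cross(
        CrossConfig(n_offspring=200, seed=11), small_genome
    )


@pytest.fixture(scope="session")
def noisy_cross(small_genome):
    """Same design with realistic genotyping noise."""
    return simulate_cross(
        CrossConfig(
            n_offspring=200, genotype_error_rate=0.002, missing_rate=0.02, seed=12
        ),
        small_genome,
    )


@pytest.fixture(scope="session")
def inversion():
    return TruthInversion("chr1", 4_000_000, 6_000_000, carrier_species="cydno", suppression=1.0)


@pytest.fixture(scope="session")
def hybrid_cross(small_genome, inversion):
    return simulate_cross(
        CrossConfig(design="hybrid_backcross", n_offspring=300, seed=13),
        small_genome,
        [inversion],
    )
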