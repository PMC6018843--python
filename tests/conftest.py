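import numpy as np
import pytest

from fuzzmap.simulate import (
    CausalLocus,
    CausalModel,
    MarkerGrid,
    SimGenome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_genome():
    """Two 5-Mb chromosomes, one marker per 500 kb."""
    return SimGenome.default(
        chrom_length=5_000_000, marker_spacing=500_000, n_chromosomes=2
    )


@pytest.fixture(scope="session")
def single_locus_model():
    return CausalModel(
        loci=(CausalLocus("A01", 2_000_000, "required_recessive", -2.0),)
    )


@pytest.fixture(scope="session")
def small_grid(small_genome, single_locus_model):
    return MarkerGrid(small_genome, single_locus_model.loci)


@pytest.fixture(scope="session")
def two_locus_model():
    return CausalModel(
        loci=(
            CausalLocus("A01", 2_000_000, "required_recessive", -2.0),
            CausalLocus("A02", 3_000_000, "required_recessive", -2.0),
        )
    )
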