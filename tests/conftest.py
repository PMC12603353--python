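import numpy as np
import pytest

from phastyle.sequence_io import ContigRecord
from phastyle.synthetic import GeneratorConfig, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_generator_config():
    """Short genomes so generator-dependent tests stay fast."""
    return GeneratorConfig(genome_len_range=(8_000, 12_000), cassettes_per_genome=12, seed=7)


@pytest.fixture
def virulent_genome(small_generator_config, rng):
    return generate_genome("virulent", small_generator_config, rng, genome_id="vir0")


@pytest.fixture
def temperate_genome(small_generator_config, rng):
    return generate_genome("temperate", small_generator_config, rng, genome_id="tem0")


@pytest.fixture
def random_contig(rng):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return ContigRecord(id="rand0", seq=seq)
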