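import random

import pytest

from prfscan.synth import PlantSiteSpec, SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def small_spec():
    """A compact planted genome spec used across tests (fast to generate)."""
    return SyntheticSpec(
        seed=42,
        utr5_len=100,
        orf_codons=600,
        utr3_len=150,
        plant_site=PlantSiteSpec(codon_index=300),
        genome_id="toyvirus",
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_genome(small_spec)


@pytest.fixture()
def rng():
    return random.Random(20240917)
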