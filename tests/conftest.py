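import pytest

from mitochar.simulate import GenomeSpec, PopulationSpec, make_genome, make_population


@pytest.fixture(scope="session")
def default_genome():
    """Synthetic genome realizing the published 39-feature layout."""
    return make_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def coi_population():
    """30 aligned 1664-bp sequences, two haplotypes (18:12) at one site."""
    spec = PopulationSpec(
        n=30, L=1664, hap_config=((18, ()), (12, (500,))), seed=3
    )
    return [s for _, s in make_population(spec)]
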