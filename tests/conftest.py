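import pytest

from xenorna.sim.references import ReferenceConfig, build_reference_pair
from xenorna.sim.reads import MixtureConfig, simulate_read_pairs, simulate_study_run


@pytest.fixture(scope="session")
def small_refpair():
    """Eight 600-bp transcript pairs with a 150-bp shared segment each."""
    return build_reference_pair(
        ReferenceConfig(n_transcripts=8, transcript_length=600, homology_fraction=0.25),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_readset(small_refpair):
    """4,000 study-composition read pairs over the small reference."""
    mix = MixtureConfig(
        n_pairs=4000,
        frac_species_A_of_assignable=0.80,
        frac_cross_mappable=0.07,
        frac_unmappable=0.30,
        seed=12,
    )
    return simulate_read_pairs(small_refpair, mix)


@pytest.fixture(scope="session")
def study_run_20k():
    """Study-profile run at 20k pairs: (reference pair, read set)."""
    return simulate_study_run(n_pairs=20_000, seed=5)
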