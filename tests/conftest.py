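import pytest

from getpcr import SimConfig, design_control_amplicon, synthetic_locus


@pytest.fixture(scope="session")
def locus_guide():
    """A 2-kb random locus with a unique central + strand guide whose cut
    triplet is fixed to ACG (controls mismatch registers in fixtures)."""
    return synthetic_locus(1, cut_triplet="ACG")


@pytest.fixture(scope="session")
def locus(locus_guide):
    return locus_guide[0]


@pytest.fixture(scope="session")
def guide(locus_guide):
    return locus_guide[1]


@pytest.fixture(scope="session")
def control(locus_guide):
    return design_control_amplicon(*locus_guide)


@pytest.fixture()
def quiet_config():
    return SimConfig(seed=11, noise_sd=0.0)


@pytest.fixture()
def noisy_config():
    return SimConfig(seed=11, noise_sd=0.1)
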