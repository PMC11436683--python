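import pytest

from mesofishery import (BioEconParams, GovParams, SimConfig, build_space,
                         lhs_sample, run_ensemble)


@pytest.fixture(scope="session")
def baseline():
    return BioEconParams(), GovParams(), SimConfig()


@pytest.fixture(scope="session")
def space():
    return build_space()


@pytest.fixture(scope="session")
def samples2k(space):
    """2,000 Latin-hypercube parameter vectors; shared across tests."""
    return lhs_sample(space, 2000, seed=123)


@pytest.fixture(scope="session")
def ens2k(samples2k):
    """Paired-run outcome table over the shared sample matrix."""
    return run_ensemble(samples2k)
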