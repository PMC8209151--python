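import numpy as np
import pytest

from mdlink import FixtureSpec, generate_network


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-scale planted-block world for fast unit tests."""
    return FixtureSpec(
        n_mirna=24, n_disease=16, n_protein=15, n_lncrna=10, n_drug=10,
        n_blocks=2, p_in=0.4, p_out=0.03, seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return generate_network(small_spec)


@pytest.fixture(scope="session")
def default_fixture():
    """The stated default world (60/40/50/30/30 nodes, 3 blocks)."""
    return generate_network(FixtureSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
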