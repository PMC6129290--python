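import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from flexcop import (
    CommunityLayout,
    make_auxotroph_ring_toy,
    make_overflow_toy,
    make_producer_consumer_toy,
    toy_phototroph,
    toy_t1,
    toy_t1_with_secretion,
)


@pytest.fixture
def t1():
    return toy_t1()


@pytest.fixture
def t1_secreting():
    return toy_t1_with_secretion()


@pytest.fixture
def phototroph():
    return toy_phototroph()


@pytest.fixture
def t1_layout_excess(t1):
    """T1 alone with effectively unlimited glucose."""
    return {"T1": t1}, CommunityLayout(
        initial_biomass={"T1": 0.01},
        medium={"glc_e": 1e4, "co2_e": 0.0},
        dt=0.1,
        horizon=2.0,
    )


@pytest.fixture(scope="session")
def toy1_bundle():
    return make_producer_consumer_toy()


@pytest.fixture(scope="session")
def toy2_bundle():
    return make_auxotroph_ring_toy()


@pytest.fixture(scope="session")
def toy3_bundle():
    return make_overflow_toy()
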