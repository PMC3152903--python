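import pytest

from mitofba import (
    FUEL_ONLY,
    FixtureSpec,
    build_minimito,
    reference_fluxes,
)


@pytest.fixture(scope="session")
def minimito():
    return build_minimito()


@pytest.fixture(scope="session")
def minimito_fuel_only():
    return build_minimito(FUEL_ONLY)


@pytest.fixture(scope="session")
def atp_reference(minimito):
    state = reference_fluxes(minimito, "OBJ_ATP")
    assert state.optimal
    return state
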