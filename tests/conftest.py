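import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from flymembrane import (
    ModulationState,
    build_channel_set,
    find_dark_rest,
    solve_balance_at_voltage,
)


@pytest.fixture(scope="session")
def channels():
    """Unmodulated channel set with the shipped calibrated maxima."""
    return build_channel_set()


@pytest.fixture(scope="session")
def dark_op(channels):
    return find_dark_rest(channels)


@pytest.fixture(scope="session")
def op_59(channels):
    return solve_balance_at_voltage(-59.0, channels)


@pytest.fixture(scope="session")
def op_41(channels):
    return solve_balance_at_voltage(-41.0, channels)


@pytest.fixture(scope="session")
def op_36(channels):
    return solve_balance_at_voltage(-36.0, channels)


@pytest.fixture(scope="session")
def serotonin_channels():
    return build_channel_set(ModulationState(serotonin=True))


@pytest.fixture(scope="session")
def pip2_channels():
    return build_channel_set(ModulationState(pip2_depleted=True))
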