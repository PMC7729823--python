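import pytest

from paddysalt import CropParams, default_pond, default_profile, get_genotype
from paddysalt.run_helpers import constant_ec_runner
from paddysalt.synth import TROPICAL, generate_weather


@pytest.fixture(scope="session")
def ir64():
    return get_genotype("IR64")


@pytest.fixture(scope="session")
def season_weather():
    """150 days of seeded tropical weather starting mid-January."""
    table = generate_weather(TROPICAL, n_years=1, seed=42)
    return table.iloc[15:165].reset_index(drop=True)


@pytest.fixture()
def profile():
    return default_profile()


@pytest.fixture()
def pond():
    return default_pond()


@pytest.fixture(scope="session")
def crop_params():
    return CropParams()


@pytest.fixture(scope="session")
def level_runner():
    """Season runner with constant measured-EC levels, one weather year."""
    return constant_ec_runner(n_years=1, seed=42)
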