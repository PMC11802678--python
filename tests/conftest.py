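import pandas as pd
import pytest
from hypothesis import settings

from oxstab.season_exposure import GrowingSeason
from oxstab.synthetic import SyntheticConfig, generate_env_series

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def alpine_env() -> pd.DataFrame:
    return generate_env_series(SyntheticConfig(seed=1, zone_profile="alpine-flat"))


@pytest.fixture(scope="session")
def foothill_env() -> pd.DataFrame:
    return generate_env_series(
        SyntheticConfig(seed=1, zone_profile="foothill-diurnal"))


@pytest.fixture(scope="session")
def alpine_gs() -> GrowingSeason:
    return GrowingSeason(pd.Timestamp("2023-06-01"), pd.Timestamp("2023-09-30"))


@pytest.fixture(scope="session")
def foothill_gs() -> GrowingSeason:
    return GrowingSeason(pd.Timestamp("2023-05-01"), pd.Timestamp("2023-09-30"))
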