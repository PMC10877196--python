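import pytest
from hypothesis import HealthCheck, settings

from meniscea import build_parameter_set, default_life_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_params():
    return build_parameter_set()
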