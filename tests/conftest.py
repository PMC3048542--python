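import pytest
from hypothesis import HealthCheck, settings

from hivaaf import load_parameters, load_region_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundled_records():
    return load_region_table()


@pytest.fixture(scope="session")
def bundled_params():
    return load_parameters()


@pytest.fixture(scope="session")
def east_record(bundled_records):
    return next(
        r for r in bundled_records if r.region == "Sub-Saharan Africa, East"
    )
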