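import math

import pytest
from hypothesis import HealthCheck, settings

from gorings import RenderConfig, summarise_records, toy_T1

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def t1_records():
    return toy_T1()


@pytest.fixture
def t1_hierarchy(t1_records):
    return summarise_records(t1_records, m=3)


@pytest.fixture
def t1_config():
    return RenderConfig(m=3)


def total_value(records):
    """Brute-force summation oracle for conservation checks."""
    return math.fsum(r.value for r in records)
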