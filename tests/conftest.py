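import pytest
from hypothesis import HealthCheck, settings

from bxlkinetics import ThermoContext, load_table2_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2():
    """Reference kinetic parameter series for both enzymes (DP 2-5)."""
    return load_table2_fixture()


@pytest.fixture(scope="session")
def ctx():
    """Default thermodynamic context: 303.15 K, c_w = 0.018 L/mol."""
    return ThermoContext()
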