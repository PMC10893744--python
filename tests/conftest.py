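import pytest
from hypothesis import HealthCheck, settings

from pancwf import victoria_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fx():
    """The bundled published Victorian inputs."""
    return victoria_fixture()


@pytest.fixture(scope="session")
def status_quo(fx):
    return fx.case_table
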