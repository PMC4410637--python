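import pytest
from hypothesis import HealthCheck, settings

from interaction_modes import build_catalog

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def catalog():
    """The 82-profile catalog, built once per session."""
    return build_catalog()
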