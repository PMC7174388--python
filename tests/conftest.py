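import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pristem.designs import one_junction_design, single_window_design
from pristem.variant_library import enumerate_variants


@pytest.fixture(scope="session")
def arti_design():
    """Full one-junction design: 11 sliding windows tiling positions 1-13."""
    return one_junction_design()


@pytest.fixture(scope="session")
def arti_library(arti_design):
    return enumerate_variants(arti_design)


@pytest.fixture(scope="session")
def window4_design():
    """Single randomized window at upper-stem positions 4-6."""
    return single_window_design(4)


@pytest.fixture(scope="session")
def window4_library(window4_design):
    return enumerate_variants(window4_design)
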