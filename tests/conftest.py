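import pytest

from var3d.catalog import default_catalog
from var3d.simulate import simulate_cohort, small_config


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cohort():
    """One small cohort shared across read-only tests."""
    return simulate_cohort(small_config(seed=11))
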