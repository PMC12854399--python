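import pytest
from hypothesis import settings

from glycea import defaults

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from glycea.cohort import CohortSpec
from glycea.costing import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cirdia():
    """Intervention-arm base-case summary (printed study values)."""
    return defaults.cirdia_summary()


@pytest.fixture(scope="session")
def hc():
    """Comparator-arm base-case summary (printed study values)."""
    return defaults.hc_summary()


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast cohort spec with the default study structure."""
    return CohortSpec(n_intervention=40, n_comparator=30, seed=11)
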