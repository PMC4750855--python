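import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lmadecomp import GeneratorConfig, generate_dataset, records_to_frame


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (34 species, 20 evergreen, seed 0)."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_frame(default_dataset):
    records, _, _ = default_dataset
    return records_to_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
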