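import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxyphen.metabolic_indices import add_indices
from oxyphen.synthetic_cohort import GeneratorConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort99():
    """Default-size synthetic cohort with indices and phenotypes appended."""
    return add_indices(generate_cohort(GeneratorConfig(n=99, seed=11)))


@pytest.fixture(scope="session")
def cohort5000():
    """Large cohort for calibration-envelope checks (seed 1, the frozen default scale)."""
    return generate_cohort(GeneratorConfig(n=5000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
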