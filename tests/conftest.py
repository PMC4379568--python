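import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hervetools as h

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def consensi():
    return h.make_synthetic_consensi(seed=0)


@pytest.fixture(scope="session")
def consensi_by_label(consensi):
    return {c.label: c for c in consensi}


@pytest.fixture(scope="session")
def reference(consensi):
    return h.make_synthetic_reference(consensi, seed=0)


@pytest.fixture(scope="session")
def cohort():
    """Default 46-element simulated cohort (published subgroup mix).

    Shares seed 0 with the ``consensi``/``reference`` fixtures so the
    simulated internals derive from the same reference provirus.
    """
    config = h.SimulationConfig(seed=0)
    elements, truths, consensi = h.generate_cohort(config)
    return config, elements, truths, consensi


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
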