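import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bfim import datagen
from bfim.datagen import SampleSizeCondition

settings.register_profile(
    "unit",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")

#: small panel design used by estimation unit tests (keeps fits fast while
#: preserving the two-cohort + reference-panel pattern structure)
TOY_SIZES = SampleSizeCondition("toy", 700, 700, 150)


@pytest.fixture(scope="session")
def model1_spec():
    return datagen.build_generating_model(1)


@pytest.fixture(scope="session")
def toy_masked(model1_spec):
    rng = np.random.default_rng(314159)
    return datagen.generate_dataset(model1_spec, TOY_SIZES, rng)


@pytest.fixture(scope="session")
def toy_complete(model1_spec):
    rng = np.random.default_rng(271828)
    return datagen.simulate_complete(model1_spec, TOY_SIZES, rng)
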