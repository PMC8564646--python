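import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ctmonitor.ddpcr import AssayConstants
from ctmonitor.simulate import CohortSimConfig


@pytest.fixture
def constants() -> AssayConstants:
    return AssayConstants()


@pytest.fixture
def small_cohort_config() -> CohortSimConfig:
    return CohortSimConfig(n_patients=60, seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
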