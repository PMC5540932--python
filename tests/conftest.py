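import numpy as np
import pytest

from raclopy.kinetics import ActivationProfile, FrameSchedule
from raclopy.synth import PhantomSpec, simulate_reference_tac


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def profile() -> ActivationProfile:
    return ActivationProfile()


@pytest.fixture(scope="session")
def reference_tac(schedule):
    return simulate_reference_tac(schedule=schedule)


@pytest.fixture(scope="session")
def mini_spec() -> PhantomSpec:
    return PhantomSpec.mini()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170802)
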