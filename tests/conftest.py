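import numpy as np
import pytest
from hypothesis import settings

from doxcycle import ScenarioConfig, build_invitro_model, build_invivo_model

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def invitro_model():
    return build_invitro_model(ScenarioConfig(kind="invitro"))


@pytest.fixture(scope="session")
def invitro_high_model():
    return build_invitro_model(ScenarioConfig(kind="invitro", nadph0="high"))


@pytest.fixture(scope="session")
def invitro_sod_model():
    return build_invitro_model(
        ScenarioConfig(kind="invitro", nadph0="high", sod=True))


@pytest.fixture(scope="session")
def eu1_model():
    return build_invivo_model(ScenarioConfig(kind="invivo",
                                             cell_line="EU1-Res", dose="high"))


@pytest.fixture(scope="session")
def eu3_model():
    return build_invivo_model(ScenarioConfig(kind="invivo",
                                             cell_line="EU3-Sens", dose="high"))


def random_states(species, n, seed, scale=1e-5):
    """Random non-negative concentration states for oracle comparisons."""
    rng = np.random.default_rng(seed)
    return [
        {s: float(v) for s, v in zip(species, scale * rng.random(len(species)))}
        for _ in range(n)
    ]
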