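import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from spikeplan import (
    Activation,
    LinearTrackTask,
    NetworkParams,
    build_track_weights,
    track_context_schedule,
    track_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def track_task():
    return LinearTrackTask()


@pytest.fixture
def toy_track():
    """Enumerable passage task: K=9, T=4, passages feasible under the
    one-step-move constraint."""
    return LinearTrackTask(T=4, passage_mid=4, passage_end=5)


def random_params(
    K: int, N: int, activation: Activation, rng: np.random.Generator, scale=1.0
) -> NetworkParams:
    return NetworkParams(
        W=rng.normal(scale=scale, size=(K, K)),
        Theta=rng.normal(scale=scale, size=(K, N)),
        theta0=np.zeros(K),
        activation=activation,
    )
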