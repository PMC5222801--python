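import numpy as np
import pytest
from hypothesis import settings

from modplast.inputs import InputEnsembleConfig, generate_ensemble
from modplast.neuron import NeuronParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 5-input correlated ensemble, 10 s, used across integration tests."""
    cfg = InputEnsembleConfig(n_inputs=5, base_rate=10.0)
    return cfg, generate_ensemble(cfg, 10.0, 123)


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParams()


def poisson_train(rng, rate, duration):
    """Homogeneous Poisson spike train as sorted times (oracle-side helper)."""
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))
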