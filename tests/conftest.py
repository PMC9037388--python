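import numpy as np
import pytest

from spafilter.core import FeatureTensor, ParticleEnsemble, SPAConfig, init_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SPAConfig(K=4, N=6, tau_bu=10.0, tau_td=10.0, phi=0.1, seed=7)


@pytest.fixture
def small_ensemble(small_config):
    return init_ensemble(small_config)


@pytest.fixture
def vector_features():
    return FeatureTensor.from_vector([2.0, 1.0, 1.0, 0.5])


def make_ensemble(states, seed=0):
    """Ensemble with prescribed states and a fresh generator."""
    return ParticleEnsemble(
        states=np.asarray(states, dtype=np.uint8),
        rng=np.random.default_rng(seed),
    )
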