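import numpy as np
import pytest

from netctrl.energy import StateMap, build_control_weights
from netctrl.graph import Connectome, NormalizedSystem, normalize_adjacency
from netctrl.synth import GeneratorConfig, make_coordinates, make_connectome, make_dataset, make_state_maps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_dataset():
    """30-node dataset shared by the slower integration-style tests."""
    return make_dataset(GeneratorConfig(n=30, k_states=6, seed=7))


@pytest.fixture(scope="session")
def random_system():
    """Normalized 8-node system from a random symmetric adjacency."""
    rng = np.random.default_rng(11)
    a = np.abs(rng.normal(size=(8, 8)))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return normalize_adjacency(Connectome(weights=a), c=0.0)


@pytest.fixture
def scalar_system():
    """1-node system with drift a = -1 (closed forms known)."""
    return NormalizedSystem(a_norm=np.array([[-1.0]]), c=1.0, lambda_max=1.0)


@pytest.fixture
def uniform_b():
    def _make(n):
        return build_control_weights("uniform", n=n)

    return _make


def random_states(n, k, seed):
    rng = np.random.default_rng(seed)
    return [StateMap(rng.normal(size=n), label=f"s{i}") for i in range(k)]
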