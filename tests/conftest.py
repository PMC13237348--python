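import numpy as np
import pytest

from acgfc.data import Connectome, EpochSet, ROIAtlas
from acgfc.synth import make_connectome


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    """10-node, 20-edge small-world graph used across unit tests."""
    return make_connectome(10, 20, 0.2, seed=42)


@pytest.fixture(scope="session")
def template_connectome() -> Connectome:
    """The study-scale template: 68 nodes, 248 edges."""
    return make_connectome(68, 248, 0.1, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def sinusoid_epochs(n_epochs=6, n_nodes=4, n_samples=200, fs=100.0, freq=6.0,
                    noise=0.0, seed=0, t0_ms=0.0) -> EpochSet:
    """Helper: labelled sinusoidal epochs with per-epoch random phases."""
    r = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    data = np.sin(2 * np.pi * freq * t[None, None, :]
                  + r.uniform(0, 2 * np.pi, (n_epochs, n_nodes, 1)))
    if noise > 0:
        data = data + r.normal(0, noise, data.shape)
    labels = np.arange(n_epochs) % 2
    subjects = np.array([f"s{i % 3}" for i in range(n_epochs)])
    return EpochSet(data, labels, subjects, fs, t0_ms)
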