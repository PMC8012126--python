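import logging

import numpy as np
import pytest

import ilfs_ecg as m

logging.getLogger("ilfs_ecg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study with a clear class effect, shared across tests."""
    cfg = m.SimulationConfig(n_subjects=4, trials_per_subject=10, delta_rr=80.0, seed=11)
    recordings, ratings, truth = m.generate_study(cfg)
    return cfg, recordings, ratings, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_separable(n=60, n_features=4, shift=3.0, seed=0):
    """Balanced two-class Gaussian toy set with a mean shift on every feature."""
    r = np.random.default_rng(seed)
    half = n // 2
    X = r.normal(size=(n, n_features))
    y = np.array([0] * half + [1] * (n - half))
    X[y == 1] += shift
    return X, y
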