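import numpy as np
import pytest

from bmdd import CountTable, Hyperparams, SimConfig, simulate_bmdd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """Tiny deterministic count table (4 samples, 3 taxa) with zeros."""
    counts = np.array(
        [
            [5, 0, 12],
            [0, 7, 3],
            [2, 2, 2],
            [9, 1, 0],
        ]
    )
    return CountTable(counts=counts)


@pytest.fixture
def small_hyper():
    return Hyperparams(
        pi=np.array([0.3, 0.5, 0.7]),
        alpha0=np.array([0.05, 0.1, 0.2]),
        alpha1=np.array([2.0, 5.0, 8.0]),
    )


def make_bmdd_truth(n=20, m=5, depth=500, seed=0, preset="separated", hyper=None):
    cfg = SimConfig(
        n_samples=n,
        n_taxa=m,
        depth_range=(depth, depth),
        preset=preset,
        hyperparams=hyper,
        seed=seed,
    )
    return simulate_bmdd(cfg), cfg
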