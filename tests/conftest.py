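import numpy as np
import pytest

from plantloc import ensemble, synthetic
from plantloc.etknn import Frame


@pytest.fixture(scope="session")
def perfect_bench():
    """Small noise-free benchmark: identical descriptors within each location."""
    cfg = synthetic.SimConfig(
        n_locations=3,
        proteins_per_location=6,
        separation=1.0,
        noise=0.0,
        length_range=(60, 90),
        seed=5,
    )
    return synthetic.generate_benchmark(cfg)


@pytest.fixture(scope="session")
def perfect_features(perfect_bench):
    return perfect_bench.features()


@pytest.fixture(scope="session")
def small_config():
    return ensemble.EnsembleConfig(k_grid=(1, 2, 3), lambda_grid=(0, 1, 2))


@pytest.fixture(scope="session")
def perfect_model(perfect_bench, perfect_features, small_config):
    return ensemble.train_model(perfect_bench.dataset, perfect_features, small_config)


@pytest.fixture
def frame2():
    return Frame(("A", "B"))


@pytest.fixture
def frame3():
    return Frame(("A", "B", "C"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
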