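import numpy as np
import pytest
from hypothesis import settings

import dendritic as dn

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: 4 classes, d=64, 2 prototypes/class,
    5% flip noise, 200 train + 200 test patterns."""
    return dn.make_benchmark(seed=1)


@pytest.fixture(scope="session")
def trained_model(benchmark):
    """One classifier trained on the benchmark (m=10, k=5); memorizes it."""
    train, _ = benchmark
    model, _ = dn.fit(train, m=10, k=5, seed=1)
    return model


def tiny_model(rng, n_classes=2, d=6, m=2, k=2, X=None):
    return dn.init_model(n_classes, d, m, k, rng, X=X)
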