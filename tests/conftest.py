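import numpy as np
import pytest

from triwalk import SyntheticConfig, generate_benchmark
from triwalk.pipeline import build_bundle


@pytest.fixture(scope="session")
def default_benchmark():
    """The default planted benchmark (100 x 80 x 30, 4 clusters, seed 7)."""
    return generate_benchmark(SyntheticConfig())


@pytest.fixture(scope="session")
def default_bundle(default_benchmark):
    return build_bundle(default_benchmark)


@pytest.fixture(scope="session")
def small_benchmark():
    """A faster planted benchmark for per-module tests."""
    return generate_benchmark(
        SyntheticConfig(n_sm=30, n_mirna=24, n_disease=10, n_clusters=3, seed=11)
    )


@pytest.fixture(scope="session")
def small_bundle(small_benchmark):
    return build_bundle(small_benchmark)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
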