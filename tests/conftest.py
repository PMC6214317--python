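import numpy as np
import pytest

from deltamaps.synthetic import run_benchmark

BENCHMARK_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full pipeline runs of the ground-truth benchmark over three seeds."""
    return [run_benchmark(seed=s) for s in BENCHMARK_SEEDS]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
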