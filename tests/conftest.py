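import numpy as np
import pytest

from dasrc import fit, generate_domains
from dasrc.core import benchmark_hyperparams
from dasrc.synthetic import default_benchmark_config


@pytest.fixture(scope="session")
def benchmark_data():
    """The default synthetic benchmark, seed 0."""
    return generate_domains(default_benchmark_config(seed=0))


@pytest.fixture(scope="session")
def benchmark_model(benchmark_data):
    """A model trained on the seed-0 benchmark with the benchmark preset."""
    Ys, Yt_lab, _ = benchmark_data
    return fit(Ys, Yt_lab, benchmark_hyperparams(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
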