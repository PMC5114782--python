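import numpy as np
import pytest

from cdg.simulate import SimConfig, make_benchmark


@pytest.fixture(scope="session")
def clean_benchmark():
    """20 synthetic genes, error-free 150 bp reads at 30x (shared fixture)."""
    return make_benchmark(SimConfig(n_genes=20, seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
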