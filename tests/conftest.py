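import numpy as np
import pytest

from motifsd import BenchmarkSpec, BindingMatrix, ExpressionMatrix, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bench():
    """A small noisy benchmark replicate for stage-level tests."""
    spec = BenchmarkSpec(m=10, N=60, n=4, K=2, noise_sd=0.3, fp_rate=0.1, fn_rate=0.1, seed=7)
    return simulate(spec)


@pytest.fixture
def tiny_xw():
    """Hand-sized aligned expression/binding pair (6 genes, 2 TFs)."""
    X = ExpressionMatrix(
        np.array([
            [1.0, 1.1, 0.9, -1.0, -1.1, -0.9],
            [2.0, 2.1, 1.9, -2.0, -2.1, -1.9],
            [0.5, 0.6, 0.4, -0.5, -0.6, -0.4],
        ]),
        ["s1", "s2", "s3"],
        [f"g{i}" for i in range(1, 7)],
    )
    W = BindingMatrix(
        np.array([
            [1.0, 0.8, 0.9, 0.0, 0.0, 0.1],
            [0.0, 0.1, 0.0, 1.0, 0.9, 0.8],
        ]),
        ["tfA", "tfB"],
        [f"g{i}" for i in range(1, 7)],
    )
    return X, W
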