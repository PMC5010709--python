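import numpy as np
import pytest

from lassobags import Block, Dataset, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(X: np.ndarray, y: np.ndarray, standardize: bool = True) -> Dataset:
    ids = [f"x{j + 1}" for j in range(X.shape[1])]
    data = Dataset(X, y, ids)
    return data.standardized() if standardize else data


@pytest.fixture
def toy_dataset(rng):
    """30 x 6 standardized Gaussian design with a known linear signal on
    the first two columns."""
    X = rng.standard_normal((30, 6))
    y = 1.5 * X[:, 0] - 0.8 * X[:, 1] + 0.1 * rng.standard_normal(30)
    return make_dataset(X, y)


@pytest.fixture
def small_sim_config():
    """Fast two-block design for pipeline-level tests."""
    blocks = [Block((1, 2), (5, 6, 7), 0.6), Block((3, 4), (8, 9), 0.5)]
    return SimConfig(n=90, p=25, n_true=4, n_relevant=9, beta_value=0.5,
                     snr=2.0, block_spec=blocks, seed=7)
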