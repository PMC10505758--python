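import numpy as np
import pytest

from wedge_sdm.grids import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_grid():
    return Grid(20, 20)


def exact_correlation_sample(n: int, R: np.ndarray, seed: int) -> np.ndarray:
    """Gaussian sample whose sample correlation matrix equals R exactly
    (whiten the empirical covariance, then color by chol(R))."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, R.shape[0]))
    X -= X.mean(axis=0)
    cov = X.T @ X / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return X @ np.linalg.cholesky(R).T
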