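import numpy as np
import pytest

from mmpso import PlantSpec, TabularDataset, make_planted_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def planted_small():
    """80-sample dataset: 2 informative, 1 redundant, 5 noise features."""
    return make_planted_dataset(
        PlantSpec(n_samples=80, n_informative=2, n_redundant=1, n_noise=5, seed=3)
    )


@pytest.fixture
def blobs():
    """Two far-separated Gaussian blobs: trivially classifiable."""
    rng = np.random.default_rng(7)
    n = 50
    X = np.vstack(
        [rng.normal(-10, 1, (n, 2)), rng.normal(10, 1, (n, 2))]
    )
    y = np.repeat([0, 1], n)
    return TabularDataset(X=X, y=y)
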