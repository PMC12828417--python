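import numpy as np
import pytest

from esomaug import EsomGrid, Scaler, TabularDataset

#: reduced-scale selection settings used throughout the suite; the
#: statistical behavior is the same as at full scale, only noisier
FAST_SELECT = dict(max_iter=12, n_trees=64)


@pytest.fixture
def blob_dataset() -> TabularDataset:
    """Two well-separated Gaussian blobs (means 0 and 10, sd 1)."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(50, 3))
    b = rng.normal(10.0, 1.0, size=(50, 3))
    return TabularDataset(
        values=np.vstack([a, b]),
        labels=np.array([1] * 50 + [2] * 50),
        feature_names=["X1", "X2", "X3"],
    )


@pytest.fixture
def labelcopy_dataset() -> TabularDataset:
    """One feature equal to the class label plus 10 pure-noise features."""
    rng = np.random.default_rng(7)
    labels = np.array([1, 2] * 30)
    noise = rng.standard_normal((60, 10))
    values = np.column_stack([labels.astype(float), noise])
    return TabularDataset(
        values=values,
        labels=labels,
        feature_names=["signal"] + [f"noise{i}" for i in range(10)],
    )


def make_grid(weights: np.ndarray, rows: int, cols: int, topology: str = "planar") -> EsomGrid:
    """Hand-built grid with an identity scaler, for structural tests."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = weights[:, None]
    return EsomGrid(
        rows=rows,
        cols=cols,
        topology=topology,
        weights=weights,
        scaler=Scaler.identity(weights.shape[1]),
    )
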