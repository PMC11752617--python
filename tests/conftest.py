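import numpy as np
import pytest
from hypothesis import settings

from spagnet import ExpressionMatrix, SpotCoordinates, make_dataset, prepare_bundle

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    values = rng.poisson(3.0, size=(6, 8)).astype(float)
    return ExpressionMatrix(values, [f"G{i}" for i in range(6)],
                            [f"S{j}" for j in range(8)])


@pytest.fixture(scope="session")
def small_dataset():
    """40-spot planted-GRN dataset shared by fast unit tests."""
    return make_dataset(n_genes=10, n_tfs=3, n_spots=40, n_regimes=2,
                        cells_per_spot=3, seed=5)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    return prepare_bundle(small_dataset.expression, small_dataset.coordinates,
                          k=4, n_pcs=8)


@pytest.fixture
def grid_coords():
    xs, ys = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
    return SpotCoordinates(np.column_stack([xs.ravel(), ys.ravel()]).astype(float))
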