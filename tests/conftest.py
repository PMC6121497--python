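import numpy as np
import pytest

from hrulci.grids import CategoricalGrid


@pytest.fixture
def random_categorical():
    """Factory for seeded random categorical rasters (optionally with nodata)."""

    def make(seed: int, shape=(10, 10), n_classes: int = 4, cell_size: float = 30.0,
             nodata_frac: float = 0.0) -> CategoricalGrid:
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, n_classes + 1, size=shape)
        mask = rng.random(shape) < nodata_frac
        if mask.all():
            mask[0, 0] = False
        return CategoricalGrid(codes, mask, cell_size,
                               {c: f"class_{c}" for c in range(1, n_classes + 1)})

    return make


@pytest.fixture
def worked_grid():
    """The 3x3 hand-traced grid: classes [[1,1,2],[1,2,2],[3,3,3]]."""
    codes = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]])
    return CategoricalGrid(codes, np.zeros((3, 3), bool), 30.0,
                           {1: "forest", 2: "cultivated", 3: "water"})
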