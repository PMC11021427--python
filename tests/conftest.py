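import numpy as np
import pytest

from habscape.raster import (
    DEFAULT_LEGEND,
    CategoricalRaster,
    GridTransform,
    Legend,
)
from habscape.synthetic import SyntheticConfig, generate_landcover

TWO_CLASS_LEGEND = Legend([(1, "habitat"), (2, "other")])


def make_categorical(values, cell_size=30.0, legend=None, nodata=0):
    values = np.asarray(values, dtype=np.int64)
    if legend is None:
        codes = sorted({int(v) for v in values.ravel() if v != nodata})
        legend = Legend([(c, f"class {c}") for c in codes])
    return CategoricalRaster(
        values, legend, nodata=nodata,
        transform=GridTransform(0.0, values.shape[0] * cell_size, cell_size),
    )


@pytest.fixture
def seven_class_landcover():
    """64x64 seeded seven-class landscape."""
    return generate_landcover(SyntheticConfig(n_rows=64, n_cols=64, seed=7))


@pytest.fixture
def checkerboard():
    v = np.indices((4, 4)).sum(axis=0) % 2 + 1
    return make_categorical(v, legend=TWO_CLASS_LEGEND)
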