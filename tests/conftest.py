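import numpy as np
import pytest

from cumniche.env_grid import EnvLayer, EnvStack


@pytest.fixture
def toy_layer():
    """3×3 layer over [0,3]°×[0,3]°, cell 1°, one masked cell (row 1, col 1)."""
    values = np.ma.MaskedArray(
        np.arange(9, dtype=float).reshape(3, 3),
        mask=[[False, False, False], [False, True, False], [False, False, False]],
    )
    return EnvLayer(name="t1", values=values, origin=(0.0, 0.0), cell_size=1.0)


@pytest.fixture
def toy_stack(toy_layer):
    second = EnvLayer(
        name="t2",
        values=np.ma.MaskedArray(
            -np.arange(9, dtype=float).reshape(3, 3), mask=toy_layer.values.mask
        ),
        origin=(0.0, 0.0),
        cell_size=1.0,
    )
    return EnvStack([toy_layer, second])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
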