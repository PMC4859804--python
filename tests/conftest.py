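import numpy as np
import pytest

from topoflat import BorderPolyline, FlatmapSpec, triangulate_strip


@pytest.fixture
def planar_rectangle():
    """Flat rectangular strip, length 10 (x, rostral at 0), width 4 (y)."""
    x = np.linspace(0, 10, 21)
    dorsal = BorderPolyline("dorsal", np.column_stack([x, np.full_like(x, 4.0), np.zeros_like(x)]))
    ventral = BorderPolyline("ventral", np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]))
    return triangulate_strip(dorsal, ventral)


@pytest.fixture
def uniform_spec():
    """Rectangular flatmap: 10 rows x 8 bins (row extent equals dv extent/ratio)."""
    return FlatmapSpec("PrS_sup", 10, np.full(10, 0.8), 1.0)


@pytest.fixture
def spec_set(uniform_spec):
    """Shared-smax spec per subdivision, rectangular grids of varying width."""
    widths = {"PrS_sup": 0.8, "PrS_deep": 0.8, "PaS_deep": 0.4, "MEC_deep": 1.0, "LEC_deep": 0.6}
    return {
        sub: FlatmapSpec(sub, 10, np.full(10, w), 1.0) for sub, w in widths.items()
    }
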