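import numpy as np
import pytest
from shapely.geometry import Polygon

from synhomeo.synthgen import BoutonGeometry


@pytest.fixture
def square_polygon():
    """4 x 4 um square bouton stand-in (nm units)."""
    return Polygon([(0, 0), (4000, 0), (4000, 4000), (0, 4000)])


@pytest.fixture
def grid_bouton(square_polygon):
    """Eight well-separated reference puncta on a grid, no target channel."""
    pts = np.array([(x, y) for x in (500, 1700, 2900) for y in (500, 1700, 2900)])[:8]
    return BoutonGeometry(polygon=square_polygon, reference=pts.astype(float),
                          target=np.empty((0, 2)))
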