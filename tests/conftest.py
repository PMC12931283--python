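import numpy as np
import pytest
from shapely.ops import unary_union

from carescape.datasets import liaoning_city_records
from carescape.io_formats import Region
from carescape.synthetic_data import make_tessellation


@pytest.fixture(scope="session")
def liaoning():
    return liaoning_city_records()


@pytest.fixture(scope="session")
def study_region():
    """Whole 2x7 tessellated study area (1400 km²) as a single Region."""
    tiles = make_tessellation(2, 7, 10.0)
    return Region(
        region_id="all", name="study area",
        polygon=unary_union([t.polygon for t in tiles]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
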