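import numpy as np
import pytest
from shapely.geometry import box

from gridherd.geodata import AdminPolygon, AdminPolygonLayer, GridSpec, Raster
from gridherd.synthetic import generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced synthetic scenario for fast unit tests."""
    return generate_scenario(seed=42, n_rows=64, n_cols=64, levels=3)


@pytest.fixture(scope="session")
def default_scenario():
    """The default study-condition scenario."""
    return generate_scenario(seed=11)


@pytest.fixture
def unit_grid():
    """10x10 one-degree grid with its upper-left corner at (0E, 10N)."""
    return GridSpec(10, 10, 0.0, 10.0, 1.0)


@pytest.fixture
def two_rectangles(unit_grid):
    """Two abutting rectangles splitting the unit grid west/east."""
    return AdminPolygonLayer(
        [
            AdminPolygon("west", box(0.0, 0.0, 5.0, 10.0), 1, "AA", 100.0),
            AdminPolygon("east", box(5.0, 0.0, 10.0, 10.0), 1, "AA", 50.0),
        ]
    )


def constant_raster(spec, value):
    return Raster(spec, np.full(spec.shape, float(value)))
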