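"""Three-way land-suitability masking and suitability-adjusted densities.

Land is partitioned into cells suitable for livestock, cells unsuitable for
environmental reasons (high elevation, steep slope, urban fabric, permanent
snow/ice -- these are modelled as true zero-density land), and cells
unsuitable for legislative reasons (strictly protected areas -- excluded
from both training and output rather than asserted to hold zero animals).

Reported counts are converted to *effective* densities on usable land: a
unit of 100 km**2 holding 100 head with half its area masked has an
effective density of 2, not 1, head km**-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    GridSpec,
    Raster,
    ZoneRaster,
    _require_same_grid,
)

SUITABLE = 1
UNSUITABLE_ENV = 2
UNSUITABLE_LEG = 3

#: Default unsuitability thresholds.
DEFAULT_MAX_ELEVATION_M = 4750.0
DEFAULT_MAX_SLOPE_PCT = 40.0
#: Protected-area category codes treated as unsuitable
#: (1=Ia, 2=Ib, 3=II, 4=III in the default code table).
DEFAULT_PROTECTED_CODES = (1, 2, 3, 4)
DEFAULT_URBAN_CODES = (22,)
DEFAULT_SNOWICE_CODES = (21,)


class UnplaceablePolygonError(ValueError):
    """A polygon reports animals but has no usable land to place them on."""


@dataclass
class SuitabilityMask:
    """Per-cell suitability category on the model grid."""

    raster: Raster  # values in {SUITABLE, UNSUITABLE_ENV, UNSUITABLE_LEG}

    @property
    def spec(self) -> GridSpec:
        return self.raster.spec

    @property
    def category(self) -> np.ndarray:
        return self.raster.values

    @property
    def suitable(self) -> np.ndarray:
        return self.category == SUITABLE

    @property
    def unsuitable_env(self) -> np.ndarray:
        return self.category == UNSUITABLE_ENV

    @property
    def unsuitable_leg(self) -> np.ndarray:
        return self.category == UNSUITABLE_LEG

    @property
    def unsuitable(self) -> np.ndarray:
        return self.category != SUITABLE


def build_suitability_mask(
    elevation: Raster,
    slope: Raster,
    landcover: Raster,
    protected: Raster,
    *,
    max_elevation_m: float = DEFAULT_MAX_ELEVATION_M,
    max_slope_pct: float = DEFAULT_MAX_SLOPE_PCT,
    urban_codes: tuple[int, ...] = DEFAULT_URBAN_CODES,
    snowice_codes: tuple[int, ...] = DEFAULT_SNOWICE_CODES,
    protected_codes: tuple[int, ...] = DEFAULT_PROTECTED_CODES,
) -> SuitabilityMask:
    """Classify every cell as suitable / environmental / legislative.

    Environmental unsuitability (elevation above the ceiling, slope above
    the gradient limit, urban or permanent snow/ice land cover) takes
    precedence over legislative (strictly protected) status: a protected
    peak above the elevation ceiling is environmental, not legislative.
    """
    _require_same_grid(elevation, slope, landcover, protected)
    lc = landcover.values
    env = (
        (elevation.values > max_elevation_m)
        | (slope.values > max_slope_pct)
        | np.isin(lc, urban_codes)
        | np.isin(lc, snowice_codes)
    )
    leg = np.isin(protected.values, protected_codes) & ~env
    cat = np.full(elevation.spec.shape, float(SUITABLE))
    cat[env] = UNSUITABLE_ENV
    cat[leg] = UNSUITABLE_LEG
    return SuitabilityMask(Raster(elevation.spec, cat))


def usable_area_per_polygon(
    mask: SuitabilityMask, areas: Raster, zones: ZoneRaster
) -> pd.DataFrame:
    """Suitable-land area (km**2) of each polygon.

    Both unsuitable categories are excluded from the denominator, matching
    the support on which final densities are defined (outputs zero both).
    Returns columns ``zone`` and ``usable_km2``.
    """
    _require_same_grid(mask.raster, areas, zones.raster)
    usable = areas.with_values(np.where(mask.suitable, areas.values, 0.0))
    from .geodata import zonal_sum

    tbl = zonal_sum(usable, zones)
    return tbl.rename(columns={"sum": "usable_km2"})


def adjusted_density(count: float, usable_area: float) -> float:
    """Effective density (head km**-2) of a reported count on usable land.

    Raises :class:`UnplaceablePolygonError` when animals are reported but
    no usable land exists; such polygons are excluded from training and
    handled at correction time.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return 0.0
    if usable_area <= 0:
        raise UnplaceablePolygonError(
            f"count {count} cannot be placed on {usable_area} km2 of usable land"
        )
    return count / usable_area
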