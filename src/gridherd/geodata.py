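"""Grid, raster and administrative-polygon data model.

All spatial data live on a single unprojected WGS84 geographic grid
(latitude/longitude degrees). A run never mixes grids: every raster must
share one :class:`GridSpec` exactly and operations fail fast on mismatch
rather than resampling.

Rasters are read and written as ESRI ASCII grids (plain-text, single band,
nodata honoured); polygon layers as GeoJSON with the attribute fields
``id``, ``level``, ``country`` and ``count``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

#: Mean (authalic) Earth radius in km: the sphere with the same surface
#: area as the WGS84 ellipsoid.
EARTH_RADIUS_KM = 6371.0088

#: Sentinel for a missing livestock count in polygon attributes.
#: Reserved for counts only -- raster nodata is declared per GridSpec.
MISSING_COUNT = -9999

_DEFAULT_NODATA = -32768.0


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """A geographic (WGS84 lat/lon) raster grid.

    The origin is the upper-left *corner* of the upper-left cell; rows run
    south, columns run east. ``cell_size`` is in decimal degrees and is the
    same in both axes.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.origin_lat > 90.0 or self.origin_lat - self.n_rows * self.cell_size < -90.0:
            raise ValueError("grid extends beyond +/-90 degrees latitude")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing the given coordinates."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def same_grid(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )


@dataclass
class Raster:
    """A single-band raster: one scalar per grid cell.

    ``values`` is a float64 array of shape ``(n_rows, n_cols)``; cells equal
    to ``spec.nodata`` are excluded from all statistics.
    """

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    @classmethod
    def full(cls, spec: GridSpec, fill: float = 0.0) -> "Raster":
        return cls(spec, np.full(spec.shape, fill, dtype=float))

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values)

    def global_sum(self) -> float:
        return float(self.values[self.valid_mask].sum())


def _require_same_grid(*rasters: Raster) -> None:
    first = rasters[0].spec
    for r in rasters[1:]:
        if not first.same_grid(r.spec):
            raise GridMismatchError("rasters are not on the same grid")


def compute_pixel_areas(spec: GridSpec, radius: float = EARTH_RADIUS_KM) -> Raster:
    """Area of each cell in km**2, from the spherical band formula.

    area(row) = R^2 * dlon_rad * (sin(lat_top) - sin(lat_bottom)), constant
    across a row of a geographic grid, shrinking with |latitude|.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lat_top = np.deg2rad(spec.origin_lat - np.arange(spec.n_rows) * spec.cell_size)
    lat_bot = np.deg2rad(spec.origin_lat - (np.arange(spec.n_rows) + 1) * spec.cell_size)
    dlon = math.radians(spec.cell_size)
    band = radius * radius * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    return Raster(spec, np.repeat(band[:, None], spec.n_cols, axis=1))


@dataclass
class AdminPolygon:
    """One administrative unit with its reported livestock count."""

    id: str
    geometry: BaseGeometry
    level: int
    country: str
    count: float  # head, or MISSING_COUNT

    @property
    def has_count(self) -> bool:
        return self.count != MISSING_COUNT


@dataclass
class AdminPolygonLayer:
    """An ordered collection of non-overlapping administrative polygons."""

    polygons: list[AdminPolygon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self):
        return iter(self.polygons)

    def __getitem__(self, i: int) -> AdminPolygon:
        return self.polygons[i]

    def by_id(self) -> dict[str, AdminPolygon]:
        return {p.id: p for p in self.polygons}

    def total_count(self) -> float:
        return float(sum(p.count for p in self.polygons if p.has_count))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AdminPolygonLayer":
        with open(path) as fh:
            gj = json.load(fh)
        polys = []
        for feat in gj["features"]:
            props = feat["properties"]
            polys.append(
                AdminPolygon(
                    id=str(props["id"]),
                    geometry=geom_shape(feat["geometry"]),
                    level=int(props["level"]),
                    country=str(props["country"]),
                    count=float(props["count"]),
                )
            )
        return cls(polys)

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": geom_mapping(p.geometry),
                "properties": {
                    "id": p.id,
                    "level": p.level,
                    "country": p.country,
                    "count": p.count,
                },
            }
            for p in self.polygons
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class ZoneRaster:
    """Integer zone codes on a grid plus the code -> token mapping."""

    raster: Raster
    codes: dict[int, str]

    #: integer nodata used inside the zone value array
    @property
    def spec(self) -> GridSpec:
        return self.raster.spec

    def id_of(self, code: int) -> str:
        return self.codes[code]

    def code_of(self, token: str) -> int:
        for c, t in self.codes.items():
            if t == token:
                return c
        raise KeyError(token)


def rasterize_polygons(layer: AdminPolygonLayer, spec: GridSpec) -> ZoneRaster:
    """Burn polygon ids into a grid by cell-centre containment.

    Each cell takes the id of the polygon containing its centre; a centre
    lying exactly on a shared edge goes to the polygon earliest in file
    order. Cells outside all polygons carry nodata.
    """
    if len(layer) == 0:
        raise ValueError("cannot rasterize an empty polygon layer")
    lon = spec.lon_centers()
    lat = spec.lat_centers()
    out = np.full(spec.shape, spec.nodata, dtype=float)
    unassigned = np.ones(spec.shape, dtype=bool)
    codes: dict[int, str] = {}
    for idx, poly in enumerate(layer):
        code = idx + 1
        codes[code] = poly.id
        minx, miny, maxx, maxy = poly.geometry.bounds
        cols = np.where((lon >= minx) & (lon <= maxx))[0]
        rows = np.where((lat >= miny) & (lat <= maxy))[0]
        if cols.size == 0 or rows.size == 0:
            continue
        gx, gy = np.meshgrid(lon[cols], lat[rows])
        # covers(): boundary counts as inside, so edge cells resolve to the
        # first polygon touched in file order via the `unassigned` guard
        inside = shapely.covers(poly.geometry, shapely.points(gx.ravel(), gy.ravel()))
        inside = inside.reshape(rows.size, cols.size)
        sub = np.ix_(rows, cols)
        hit = inside & unassigned[sub]
        block = out[sub]
        block[hit] = code
        out[sub] = block
        ua = unassigned[sub]
        ua[hit] = False
        unassigned[sub] = ua
    return ZoneRaster(Raster(spec, out), codes)


def rasterize_countries(layer: AdminPolygonLayer, spec: GridSpec) -> ZoneRaster:
    """Burn country codes (one zone per distinct country) into a grid."""
    zones = rasterize_polygons(layer, spec)
    countries = sorted({p.country for p in layer})
    code_of = {c: i + 1 for i, c in enumerate(countries)}
    remap = {pc + 1: code_of[p.country] for pc, p in enumerate(layer)}
    vals = zones.raster.values
    out = np.full(spec.shape, spec.nodata)
    for old, new in remap.items():
        out[vals == old] = new
    return ZoneRaster(Raster(spec, out), {v: k for k, v in code_of.items()})


def zonal_sum(value_raster: Raster, zones: ZoneRaster) -> pd.DataFrame:
    """Sum of non-nodata values per zone; nodata cells contribute zero.

    Returns a DataFrame with columns ``zone`` (token) and ``sum``; zones
    absent from the zone raster do not appear.
    """
    _require_same_grid(value_raster, zones.raster)
    zvals = zones.raster.values
    in_zone = zones.raster.valid_mask
    vals = np.where(value_raster.valid_mask, value_raster.values, 0.0)
    if not in_zone.any():
        return pd.DataFrame({"zone": pd.Series([], dtype=str), "sum": pd.Series([], dtype=float)})
    codes = zvals[in_zone].astype(int)
    sums = np.bincount(codes, weights=vals[in_zone])
    present = np.unique(codes)
    return pd.DataFrame(
        {"zone": [zones.codes[int(c)] for c in present], "sum": sums[present]}
    )


def zonal_sum_dict(value_raster: Raster, zones: ZoneRaster) -> dict[str, float]:
    tbl = zonal_sum(value_raster, zones)
    return dict(zip(tbl["zone"], tbl["sum"]))


# ---------------------------------------------------------------------------
# ASCII-grid I/O

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (text, row order north->south)."""
    spec = raster.spec
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_lon!r}\n"
        f"yllcorner {spec.origin_lat - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", _DEFAULT_NODATA),
    )
    return Raster(spec, values)
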