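"""Sample-point selection and the bootstrap train/test structure.

The dependent variable is the suitability-adjusted livestock density of a
point's polygon, transformed to log10(density + 1) to normalise its
distribution. Points are drawn at a target density of 30 per 10,000 km**2
with at least one point per polygon, so every polygon smaller than
10,000/30 ~ 333 km**2 contributes exactly one point.

The bootstrap structure is n_files independent point files (fresh random
placements of the full point set) x n_selections random 75/25 train/test
splits within each file -- 25 bootstraps by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import AdminPolygonLayer, Raster, ZoneRaster, rasterize_polygons, _require_same_grid
from .masking import (
    SuitabilityMask,
    UnplaceablePolygonError,
    adjusted_density,
    UNSUITABLE_LEG,
)

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_DENSITY = 30.0  # points per 10,000 km2
REFERENCE_AREA_KM2 = 10_000.0


def transform_density(d):
    """log10(d + 1) of a density in head km**-2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    return np.log10(d + 1.0)


def inverse_transform(y):
    """Back-transform log10(d + 1) to density, clipping negatives to zero."""
    return np.maximum(0.0, np.power(10.0, np.asarray(y, dtype=float)) - 1.0)


def minimum_guaranteed_area(density: float = DEFAULT_SAMPLE_DENSITY) -> float:
    """Polygon area (km**2) below which the expected point count drops
    under one, so the one-point-per-polygon floor applies."""
    return REFERENCE_AREA_KM2 / density


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_sample_points(
    layer: AdminPolygonLayer,
    mask: SuitabilityMask,
    areas: Raster,
    density: float = DEFAULT_SAMPLE_DENSITY,
    seed: int | np.random.Generator | None = None,
    *,
    zones: ZoneRaster | None = None,
) -> pd.DataFrame:
    """Draw one file of sample points from the training polygons.

    Per polygon with an observed count, n = max(1, round(area * density /
    10,000)) points are placed on its non-legislative cells, a cell chosen
    with probability proportional to its area and the point uniform within
    the cell. Points on environmentally unsuitable cells are retained with
    zero density; legislative cells never receive points. Polygons without
    an eligible cell, without a count, or with animals but no usable land
    are skipped and flagged.

    Returns a DataFrame with columns lon, lat, row, col, polygon_id,
    country, density, y, in_env_mask; skipped polygon ids are recorded in
    ``df.attrs["skipped"]``.
    """
    if len(layer) == 0:
        raise ValueError("empty polygon layer")
    _require_same_grid(mask.raster, areas)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if zones is None:
        zones = rasterize_polygons(layer, mask.spec)
    _require_same_grid(mask.raster, zones.raster)
    spec = mask.spec

    zvals = zones.raster.values
    suitable = mask.suitable
    env = mask.unsuitable_env
    records: list[tuple] = []
    skipped: list[str] = []
    for idx, poly in enumerate(layer):
        code = idx + 1
        cell_rows, cell_cols = np.nonzero(zvals == code)
        if cell_rows.size == 0:
            skipped.append(poly.id)
            continue
        if not poly.has_count:
            skipped.append(poly.id)
            continue
        cell_area = areas.values[cell_rows, cell_cols]
        land_area = float(cell_area.sum())
        s = suitable[cell_rows, cell_cols]
        usable = float(cell_area[s].sum())
        try:
            dens = adjusted_density(poly.count, usable)
        except UnplaceablePolygonError:
            skipped.append(poly.id)
            logger.warning("polygon %s has animals but no usable land; skipped", poly.id)
            continue
        eligible = ~ (mask.unsuitable_leg[cell_rows, cell_cols])
        if not eligible.any():
            skipped.append(poly.id)
            continue
        n_pts = max(1, _round_half_up(land_area * density / REFERENCE_AREA_KM2))
        w = cell_area[eligible]
        pick = rng.choice(np.nonzero(eligible)[0], size=n_pts, p=w / w.sum())
        rr = cell_rows[pick]
        cc = cell_cols[pick]
        lon = spec.origin_lon + (cc + rng.random(n_pts)) * spec.cell_size
        lat = spec.origin_lat - (rr + rng.random(n_pts)) * spec.cell_size
        on_env = env[rr, cc]
        d_pt = np.where(on_env, 0.0, dens)
        for k in range(n_pts):
            records.append(
                (lon[k], lat[k], int(rr[k]), int(cc[k]), poly.id, poly.country,
                 d_pt[k], float(transform_density(d_pt[k])), bool(on_env[k]))
            )
    df = pd.DataFrame(
        records,
        columns=["lon", "lat", "row", "col", "polygon_id", "country",
                 "density", "y", "in_env_mask"],
    )
    df.attrs["skipped"] = skipped
    return df


def build_sample_files(
    layer: AdminPolygonLayer,
    mask: SuitabilityMask,
    areas: Raster,
    density: float = DEFAULT_SAMPLE_DENSITY,
    n_files: int = 5,
    seed: int | None = None,
    *,
    zones: ZoneRaster | None = None,
) -> pd.DataFrame:
    """Draw ``n_files`` independent point files (fresh placements each),
    concatenated with a ``file`` column."""
    if zones is None:
        zones = rasterize_polygons(layer, mask.spec)
    streams = np.random.SeedSequence(seed).spawn(n_files)
    parts = []
    skipped: list[str] = []
    for f, ss in enumerate(streams):
        pts = select_sample_points(
            layer, mask, areas, density, np.random.default_rng(ss), zones=zones
        )
        pts.insert(0, "file", f)
        skipped = pts.attrs["skipped"]
        parts.append(pts)
    out = pd.concat(parts, ignore_index=True)
    out.attrs["skipped"] = skipped
    return out


@dataclass
class BootstrapPlan:
    """Train/test role assignments: one entry per (file, selection) pair."""

    n_files: int
    n_selections: int
    train_fraction: float
    seed: int | None
    #: (file, selection) -> boolean train mask over the rows of the point
    #: DataFrame (False rows of that file are its test set; rows of other
    #: files are all False).
    train_masks: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def bootstrap_ids(self) -> list[tuple[int, int]]:
        return sorted(self.train_masks)

    def train_index(self, bid: tuple[int, int]) -> np.ndarray:
        return np.nonzero(self.train_masks[bid])[0]

    def test_index(self, bid: tuple[int, int], file_col: np.ndarray) -> np.ndarray:
        mask = (file_col == bid[0]) & ~self.train_masks[bid]
        return np.nonzero(mask)[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (f, s), m in sorted(self.train_masks.items()):
            in_file = np.nonzero(m)[0]
            rows += [(f, s, int(i), "train") for i in in_file]
        return pd.DataFrame(rows, columns=["file", "selection", "point", "role"])


def assign_bootstraps(
    points: pd.DataFrame,
    n_selections: int = 5,
    train_fraction: float = 0.75,
    seed: int | None = None,
) -> BootstrapPlan:
    """Random 75/25 train/test splits within each point file.

    The train size is round-half-up of ``train_fraction * n`` capped so at
    least one test point remains; fully reproducible from the seed.
    """
    if "file" not in points.columns:
        points = points.assign(file=0)
    files = sorted(points["file"].unique())
    n_total = len(points)
    plan = BootstrapPlan(len(files), n_selections, train_fraction, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    file_col = points["file"].to_numpy()
    for f in files:
        rows = np.nonzero(file_col == f)[0]
        n = rows.size
        if n < 4:
            raise ValueError(f"file {f}: need at least 4 points, got {n}")
        n_train = min(_round_half_up(train_fraction * n), n - 1)
        if n_train < 1:
            raise ValueError(f"file {f}: empty training set")
        for s in range(n_selections):
            chosen = rng.choice(rows, size=n_train, replace=False)
            m = np.zeros(n_total, dtype=bool)
            m[chosen] = True
            plan.train_masks[(int(f), s)] = m
    return plan


def extract_point_data(
    points: pd.DataFrame,
    covariates: dict[str, Raster],
    strata: dict[str, Raster],
) -> pd.DataFrame:
    """Attach covariate values and stratum codes at each point's cell.

    Points falling on a nodata cell of any covariate are dropped; the drop
    count is logged and recorded in ``df.attrs["n_dropped"]``.
    """
    rr = points["row"].to_numpy()
    cc = points["col"].to_numpy()
    out = points.copy()
    keep = np.ones(len(points), dtype=bool)
    for name, rast in covariates.items():
        v = rast.values[rr, cc]
        keep &= v != rast.spec.nodata
        out[f"cov_{name}"] = v
    for name, rast in strata.items():
        out[f"stratum_{name}"] = rast.values[rr, cc].astype(int)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d points on covariate nodata", n_dropped)
    out = out[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    out.attrs.update(points.attrs)
    return out
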