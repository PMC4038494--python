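"""Mass-conserving corrections, the pig cultural mask, and aggregation.

Modelled densities are first rescaled within every polygon that reported a
count so predicted totals match the census exactly (polygons with the
-9999 missing sentinel keep their modelled densities), then rescaled per
country to match official national totals, and -- for pigs only -- zeroed
in countries where all three conditions of the cultural exclusion rule
hold. Aggregation to coarser grids operates on head counts, never on
densities, so totals are conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    AdminPolygonLayer,
    GridSpec,
    MISSING_COUNT,
    Raster,
    ZoneRaster,
    _require_same_grid,
)
from .masking import SuitabilityMask

logger = logging.getLogger(__name__)

MATCH_RTOL = 1e-6


@dataclass
class CorrectionReport:
    """Per-polygon (or per-country) totals before/after correction."""

    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def correct_to_polygons(
    density: Raster,
    layer: AdminPolygonLayer,
    areas: Raster,
    mask: SuitabilityMask,
    *,
    zones: ZoneRaster | None = None,
) -> tuple[Raster, CorrectionReport]:
    """Scale densities within each observed polygon so its modelled total
    equals the reported count.

    Polygons whose modelled total is zero but whose count is positive get
    the count spread uniformly over their suitable pixels (over all their
    pixels when none is suitable, with a warning). Missing-count polygons
    are untouched.
    """
    _require_same_grid(density, areas, mask.raster)
    from .geodata import rasterize_polygons

    if zones is None:
        zones = rasterize_polygons(layer, density.spec)
    _require_same_grid(density, zones.raster)
    out = density.values.copy()
    valid = density.valid_mask
    zvals = zones.raster.values
    rows = []
    for idx, poly in enumerate(layer):
        code = idx + 1
        cells = (zvals == code) & valid
        head = np.where(cells, out * areas.values, 0.0)
        modelled = float(head.sum())
        if not poly.has_count:
            rows.append((poly.id, poly.count, modelled, np.nan, False))
            continue
        if modelled > 0:
            factor = poly.count / modelled
            out[cells] *= factor
            rows.append((poly.id, poly.count, modelled, factor, False))
        elif poly.count == 0:
            out[cells] = 0.0
            rows.append((poly.id, poly.count, modelled, 0.0, False))
        else:
            target = cells & mask.suitable
            unplaceable = not target.any()
            if unplaceable:
                target = cells
                logger.warning(
                    "polygon %s: count %s spread over unsuitable land",
                    poly.id, poly.count,
                )
            area = float(areas.values[target].sum())
            out[target] = poly.count / area
            rows.append((poly.id, poly.count, modelled, np.nan, unplaceable))
    report = CorrectionReport(
        pd.DataFrame(
            rows,
            columns=["polygon_id", "count", "modelled_total", "scale_factor",
                     "unplaceable"],
        )
    )
    return Raster(density.spec, out), report


def correct_to_national(
    density: Raster,
    national_totals: pd.DataFrame,
    country_zones: ZoneRaster,
    areas: Raster,
    *,
    species: str | None = None,
    mask: SuitabilityMask | None = None,
) -> tuple[Raster, CorrectionReport]:
    """Uniform per-country rescaling so gridded totals match the national
    statistics table (columns ``country``, ``species``, ``total``).

    Countries absent from the table are left unchanged and logged.
    """
    _require_same_grid(density, country_zones.raster, areas)
    totals = national_totals
    if species is not None and "species" in totals.columns:
        totals = totals[totals["species"] == species]
    target = dict(zip(totals["country"], totals["total"].astype(float)))
    out = density.values.copy()
    valid = density.valid_mask
    zvals = country_zones.raster.values
    rows = []
    for code, country in country_zones.codes.items():
        cells = (zvals == code) & valid
        modelled = float((out[cells] * areas.values[cells]).sum())
        if country not in target:
            logger.info("country %s has no national total; left unchanged", country)
            rows.append((country, modelled, np.nan, np.nan))
            continue
        t = target[country]
        if t == 0:
            out[cells] = 0.0
            rows.append((country, modelled, t, 0.0))
        elif modelled > 0:
            factor = t / modelled
            out[cells] *= factor
            rows.append((country, modelled, t, factor))
        else:
            spread = cells & mask.suitable if mask is not None else cells
            if not spread.any():
                spread = cells
            logger.warning(
                "country %s: no modelled animals; total %s spread uniformly",
                country, t,
            )
            area = float(areas.values[spread].sum())
            out[spread] = t / area
            rows.append((country, modelled, t, np.nan))
    report = CorrectionReport(
        pd.DataFrame(rows, columns=["country", "modelled_total", "national_total",
                                    "scale_factor"])
    )
    return Raster(density.spec, out), report


def apply_pig_mask(
    density: Raster,
    attributes: pd.DataFrame,
    country_zones: ZoneRaster,
) -> Raster:
    """Zero all pixels of countries meeting the pig exclusion rule.

    A country is zeroed iff (1) more than 50% of its population is Muslim,
    (2) sub-national data report zero or no pigs, and (3) the national
    statistics report zero or no pigs while reporting other livestock
    species. ``attributes`` columns: country, percent_muslim,
    has_subnational_pig_data, national_pig_total, national_other_total
    (NaN = no data). Countries missing from the table are skipped with a
    warning. Idempotent.
    """
    _require_same_grid(density, country_zones.raster)
    attrs = attributes.set_index("country")
    out = density.values.copy()
    zvals = country_zones.raster.values
    for code, country in country_zones.codes.items():
        if country not in attrs.index:
            logger.warning("country %s missing from attribute table; skipped", country)
            continue
        row = attrs.loc[country]
        muslim_majority = float(row["percent_muslim"]) > 50.0
        no_subnational = not bool(row["has_subnational_pig_data"])
        pig = row["national_pig_total"]
        other = row["national_other_total"]
        no_national_pigs = pd.isna(pig) or float(pig) == 0.0
        reports_other = not pd.isna(other) and float(other) > 0.0
        if muslim_majority and no_subnational and no_national_pigs and reports_other:
            cells = (zvals == code) & density.valid_mask
            out[cells] = 0.0
    return Raster(density.spec, out)


def density_to_numbers(density: Raster, areas: Raster) -> Raster:
    """head km**-2 -> head per pixel."""
    _require_same_grid(density, areas)
    out = np.where(density.valid_mask, density.values * areas.values,
                   density.spec.nodata)
    return Raster(density.spec, out)


def numbers_to_density(counts: Raster, areas: Raster) -> Raster:
    _require_same_grid(counts, areas)
    out = np.where(counts.valid_mask, counts.values / areas.values,
                   counts.spec.nodata)
    return Raster(counts.spec, out)


def aggregate(counts: Raster, factor: int) -> Raster:
    """Block-sum a head-count raster by an integer factor.

    Grids not divisible by the factor are padded with nodata; nodata cells
    contribute zero unless the whole block is nodata, which stays nodata.
    The global total is conserved exactly.
    """
    if factor < 2:
        raise ValueError("aggregation factor must be at least 2")
    spec = counts.spec
    pr = (-spec.n_rows) % factor
    pc = (-spec.n_cols) % factor
    vals = np.pad(counts.values, ((0, pr), (0, pc)), constant_values=spec.nodata)
    valid = vals != spec.nodata
    filled = np.where(valid, vals, 0.0)
    nr, nc = vals.shape[0] // factor, vals.shape[1] // factor
    blocks = filled.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    any_valid = valid.reshape(nr, factor, nc, factor).any(axis=(1, 3))
    out = np.where(any_valid, blocks, spec.nodata)
    new_spec = GridSpec(
        n_rows=nr,
        n_cols=nc,
        origin_lon=spec.origin_lon,
        origin_lat=spec.origin_lat,
        cell_size=spec.cell_size * factor,
        nodata=spec.nodata,
    )
    return Raster(new_spec, out)
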