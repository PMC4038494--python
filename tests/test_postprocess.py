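"""Mass-conserving corrections, pig mask, unit conversion, aggregation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from gridherd.geodata import (
    MISSING_COUNT,
    AdminPolygon,
    AdminPolygonLayer,
    GridSpec,
    Raster,
    compute_pixel_areas,
    rasterize_polygons,
)
from gridherd.masking import SUITABLE, UNSUITABLE_ENV, SuitabilityMask
from gridherd.postprocess import (
    aggregate,
    apply_pig_mask,
    correct_to_national,
    correct_to_polygons,
    density_to_numbers,
    numbers_to_density,
)


@pytest.fixture
def world():
    spec = GridSpec(4, 4, 0.0, 2.0, 0.5)
    areas = compute_pixel_areas(spec)
    mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
    layer = AdminPolygonLayer(
        [
            AdminPolygon("w", box(0, 0, 1, 2), 1, "AA", 100.0),
            AdminPolygon("e", box(1, 0, 2, 2), 1, "BB", MISSING_COUNT),
        ]
    )
    return spec, areas, mask, layer


class TestPolygonCorrection:
    def test_proportional_scaling(self, world):
        spec, areas, mask, layer = world
        dens = Raster(spec, np.full(spec.shape, 1.0))
        corrected, rep = correct_to_polygons(dens, layer, areas, mask)
        zones = rasterize_polygons(layer, spec)
        w = zones.raster.values == 1
        total = (corrected.values * areas.values)[w].sum()
        assert total == pytest.approx(100.0, rel=1e-9)
        row = rep.rows.set_index("polygon_id").loc["w"]
        assert row["scale_factor"] == pytest.approx(100.0 / row["modelled_total"])

    def test_missing_count_untouched(self, world):
        spec, areas, mask, layer = world
        dens = Raster(spec, np.full(spec.shape, 1.0))
        corrected, _ = correct_to_polygons(dens, layer, areas, mask)
        zones = rasterize_polygons(layer, spec)
        e = zones.raster.values == 2
        np.testing.assert_array_equal(corrected.values[e], dens.values[e])

    def test_zero_modelled_total_spreads_uniformly(self, world):
        spec, areas, mask, layer = world
        dens = Raster(spec, np.zeros(spec.shape))
        corrected, rep = correct_to_polygons(dens, layer, areas, mask)
        zones = rasterize_polygons(layer, spec)
        w = zones.raster.values == 1
        expected = 100.0 / areas.values[w].sum()
        assert np.allclose(corrected.values[w], expected)

    def test_spread_respects_suitability(self, world):
        spec, areas, _, layer = world
        cat = np.full(spec.shape, float(SUITABLE))
        cat[:2, :] = UNSUITABLE_ENV
        mask = SuitabilityMask(Raster(spec, cat))
        dens = Raster(spec, np.zeros(spec.shape))
        corrected, _ = correct_to_polygons(dens, layer, areas, mask)
        zones = rasterize_polygons(layer, spec)
        w = zones.raster.values == 1
        assert np.all(corrected.values[w & (cat == UNSUITABLE_ENV)] == 0.0)
        assert np.all(corrected.values[w & (cat == SUITABLE)] > 0.0)

    def test_every_observed_polygon_conserved(self, small_scenario):
        sc = small_scenario
        lvl = sc.finest_level
        rng = np.random.default_rng(0)
        modelled = Raster(sc.spec, sc.true_density.values * rng.uniform(0.5, 2.0, sc.spec.shape))
        corrected, _ = correct_to_polygons(modelled, sc.layers[lvl], sc.areas, sc.mask)
        zones = rasterize_polygons(sc.layers[lvl], sc.spec)
        head = Raster(sc.spec, corrected.values * sc.areas.values)
        from gridherd.geodata import zonal_sum_dict

        sums = zonal_sum_dict(head, zones)
        for p in sc.layers[lvl]:
            assert abs(sums.get(p.id, 0.0) - p.count) / max(p.count, 1.0) < 1e-6


class TestNationalCorrection:
    def test_scaling_to_total(self, world):
        spec, areas, mask, layer = world
        zones = rasterize_polygons(
            AdminPolygonLayer([AdminPolygon("AA", box(0, 0, 2, 2), 0, "AA", 0.0)]), spec
        )
        zones.codes[1] = "AA"
        dens = Raster(spec, np.full(spec.shape, 1.0))
        totals = pd.DataFrame({"country": ["AA"], "species": ["cattle"], "total": [2e3]})
        corrected, rep = correct_to_national(dens, totals, zones, areas, species="cattle")
        total = (corrected.values * areas.values).sum()
        assert total == pytest.approx(2e3, rel=1e-9)

    def test_missing_total_unchanged(self, world):
        spec, areas, mask, layer = world
        zones = rasterize_polygons(
            AdminPolygonLayer([AdminPolygon("AA", box(0, 0, 2, 2), 0, "AA", 0.0)]), spec
        )
        dens = Raster(spec, np.full(spec.shape, 1.0))
        totals = pd.DataFrame({"country": ["ZZ"], "species": ["cattle"], "total": [5.0]})
        corrected, _ = correct_to_national(dens, totals, zones, areas)
        np.testing.assert_array_equal(corrected.values, dens.values)

    def test_zero_total_zeroes_country(self, world):
        spec, areas, mask, layer = world
        zones = rasterize_polygons(
            AdminPolygonLayer([AdminPolygon("AA", box(0, 0, 2, 2), 0, "AA", 0.0)]), spec
        )
        dens = Raster(spec, np.full(spec.shape, 1.0))
        totals = pd.DataFrame({"country": ["AA"], "total": [0.0]})
        corrected, _ = correct_to_national(dens, totals, zones, areas)
        assert np.all(corrected.values == 0.0)

    def test_national_step_perturbs_polygon_matches(self, world):
        # the sequential order is deliberate: national matching breaks the
        # exact polygon-level matches made just before
        spec, areas, mask, layer = world
        dens = Raster(spec, np.full(spec.shape, 1.0))
        corrected, _ = correct_to_polygons(dens, layer, areas, mask)
        zones0 = rasterize_polygons(
            AdminPolygonLayer([AdminPolygon("AA", box(0, 0, 2, 2), 0, "AA", 0.0)]), spec
        )
        modelled = (corrected.values * areas.values).sum()
        totals = pd.DataFrame({"country": ["AA"], "total": [modelled * 1.5]})
        after, _ = correct_to_national(corrected, totals, zones0, areas)
        z = rasterize_polygons(layer, spec)
        w = z.raster.values == 1
        poly_total = (after.values * areas.values)[w].sum()
        assert poly_total == pytest.approx(150.0, rel=1e-9)  # no longer 100


class TestPigMask:
    def _zones(self, spec):
        layer = AdminPolygonLayer([AdminPolygon("AA", box(0, 0, 2, 2), 0, "AA", 0.0)])
        return rasterize_polygons(layer, spec)

    def _attrs(self, muslim=60.0, subnat=False, pig=np.nan, other=1e6):
        return pd.DataFrame(
            {"country": ["AA"], "percent_muslim": [muslim],
             "has_subnational_pig_data": [subnat],
             "national_pig_total": [pig], "national_other_total": [other]}
        )

    def test_all_three_conditions_zero_the_country(self, world):
        spec, *_ = world
        dens = Raster(spec, np.full(spec.shape, 3.0))
        out = apply_pig_mask(dens, self._attrs(), self._zones(spec))
        assert np.all(out.values == 0.0)

    def test_reported_pigs_block_masking(self, world):
        spec, *_ = world
        dens = Raster(spec, np.full(spec.shape, 3.0))
        out = apply_pig_mask(dens, self._attrs(pig=5e5), self._zones(spec))
        np.testing.assert_array_equal(out.values, dens.values)

    def test_minority_muslim_blocks_masking(self, world):
        spec, *_ = world
        dens = Raster(spec, np.full(spec.shape, 3.0))
        out = apply_pig_mask(dens, self._attrs(muslim=40.0), self._zones(spec))
        np.testing.assert_array_equal(out.values, dens.values)

    def test_idempotent(self, world):
        spec, *_ = world
        dens = Raster(spec, np.full(spec.shape, 3.0))
        once = apply_pig_mask(dens, self._attrs(), self._zones(spec))
        twice = apply_pig_mask(once, self._attrs(), self._zones(spec))
        np.testing.assert_array_equal(once.values, twice.values)


class TestUnitsAndAggregation:
    def test_density_count_round_trip(self, world):
        spec, areas, *_ = world
        rng = np.random.default_rng(2)
        dens = Raster(spec, rng.random(spec.shape))
        back = numbers_to_density(density_to_numbers(dens, areas), areas)
        np.testing.assert_allclose(back.values, dens.values, rtol=1e-12)

    def test_block_sum_conserves_total(self):
        spec = GridSpec(10, 10, 0.0, 5.0, 0.5)
        rng = np.random.default_rng(3)
        counts = Raster(spec, rng.random(spec.shape))
        agg = aggregate(counts, 5)
        assert agg.spec.shape == (2, 2)
        assert agg.spec.cell_size == 2.5
        assert agg.values.sum() == pytest.approx(counts.values.sum(), rel=1e-12)

    def test_all_nodata_block_stays_nodata(self):
        spec = GridSpec(4, 4, 0.0, 2.0, 0.5)
        vals = np.ones(spec.shape)
        vals[:2, :2] = spec.nodata
        agg = aggregate(Raster(spec, vals), 2)
        assert agg.values[0, 0] == spec.nodata
        assert agg.values[1, 1] == 4.0

    def test_whole_grid_block(self):
        spec = GridSpec(4, 4, 0.0, 2.0, 0.5)
        counts = Raster(spec, np.ones(spec.shape))
        agg = aggregate(counts, 4)
        assert agg.spec.shape == (1, 1)
        assert agg.values[0, 0] == 16.0

    def test_factor_below_two_rejected(self):
        spec = GridSpec(4, 4, 0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            aggregate(Raster(spec, np.ones(spec.shape)), 1)
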