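"""Scheme prediction, composites, evaluation and ensembling."""

import numpy as np
import pandas as pd
import pytest

from gridherd.geodata import GridSpec, Raster
from gridherd.masking import SUITABLE, UNSUITABLE_ENV, SuitabilityMask
from gridherd.mosaic import (
    BEST_R2,
    BEST_RSE,
    COMPOSITE_R2,
    COMPOSITE_RSE,
    VARIANT_UNSTRATIFIED,
    compose_best,
    ensemble_aggregate,
    evaluate,
    predict_scheme,
    select_final,
)
from gridherd.regression import ModelSet, StratumModel, UNSTRATIFIED


def _model(intercept, scheme="A", stratum=1, r2=0.5, rse=0.5, terms=()):
    nt = len(terms)
    return StratumModel(
        scheme=scheme, stratum=stratum, terms=list(terms),
        means=np.zeros(nt), sds=np.ones(nt),
        beta=np.array([intercept] + [0.0] * (2 * nt)),
        n_points=50, n_unique=35, aic_trace=[0.0],
        r2=r2, rse=rse, loglik=0.0,
    )


@pytest.fixture
def spec():
    return GridSpec(4, 4, 0.0, 4.0, 1.0)


@pytest.fixture
def cov(spec):
    return {"c": Raster(spec, np.linspace(0, 1, 16).reshape(4, 4))}


class TestPredictScheme:
    def test_intercept_only_gives_uniform_raster(self, spec, cov):
        strat = Raster(spec, np.ones(spec.shape))
        p = predict_scheme({1: _model(1.5)}, cov, ["c"], strat, _model(9.0))
        assert np.all(p.log_raster.values == 1.5)
        assert not p.fallback.any()

    def test_refused_stratum_uses_fallback_flagged(self, spec, cov):
        strat = Raster(spec, np.array([[1.0] * 4] * 2 + [[2.0] * 4] * 2))
        p = predict_scheme({1: _model(1.5)}, cov, ["c"], strat, _model(9.0))
        assert np.all(p.log_raster.values[2:] == 9.0)
        assert p.fallback[2:].all() and not p.fallback[:2].any()

    def test_identical_covariates_identical_predictions(self, spec):
        cov = {"c": Raster(spec, np.full(spec.shape, 0.3))}
        m = _model(0.0, terms=["c"])
        m.beta = np.array([1.0, 2.0, 0.5])
        strat = Raster(spec, np.ones(spec.shape))
        p = predict_scheme({1: m}, cov, ["c"], strat, _model(0.0))
        assert np.unique(p.log_raster.values).size == 1

    def test_covariate_nodata_propagates(self, spec):
        vals = np.full(spec.shape, 0.3)
        vals[0, 0] = spec.nodata
        cov = {"c": Raster(spec, vals)}
        strat = Raster(spec, np.ones(spec.shape))
        p = predict_scheme({1: _model(1.0)}, cov, ["c"], strat, _model(0.0))
        assert p.log_raster.values[0, 0] == spec.nodata


def _two_scheme_setup(spec, cov):
    stratA = Raster(spec, np.ones(spec.shape))
    stratB = Raster(spec, np.ones(spec.shape))
    ms = ModelSet(cov_names=["c"], schemes=["A", "B"])
    bid = (0, 0)
    ms.models[(0, 0, "A", 1)] = _model(1.0, "A", r2=0.8, rse=0.3)
    ms.models[(0, 0, "B", 1)] = _model(2.0, "B", r2=0.6, rse=0.5)
    ms.unstratified[bid] = _model(5.0, UNSTRATIFIED, UNSTRATIFIED)
    preds = {
        s: predict_scheme(
            ms.stratum_models(bid, s), cov, ["c"],
            {"A": stratA, "B": stratB}[s], ms.unstratified[bid],
            bootstrap_id=bid, scheme=s,
        )
        for s in ["A", "B"]
    }
    un = predict_scheme({}, cov, ["c"], stratA, ms.unstratified[bid]).log_raster
    return {"A": stratA, "B": stratB}, ms, preds, un, bid


class TestComposeBest:
    def test_lowest_rse_wins(self, spec, cov):
        strata, ms, preds, un, bid = _two_scheme_setup(spec, cov)
        comp = compose_best(preds, strata, ms, BEST_RSE,
                            bootstrap_id=bid, unstratified_raster=un)
        assert np.all(comp.log_raster.values == 1.0)  # scheme A, RSE 0.3
        assert np.all(comp.provenance == 1)

    def test_highest_r2_wins(self, spec, cov):
        strata, ms, preds, un, bid = _two_scheme_setup(spec, cov)
        comp = compose_best(preds, strata, ms, BEST_R2,
                            bootstrap_id=bid, unstratified_raster=un)
        assert np.all(comp.log_raster.values == 1.0)  # scheme A, R2 0.8

    def test_uncovered_pixels_fall_back_with_provenance_zero(self, spec, cov):
        strata, ms, preds, un, bid = _two_scheme_setup(spec, cov)
        # remove both real models: every pixel falls back
        ms.models.clear()
        preds = {
            s: predict_scheme({}, cov, ["c"], strata[s], ms.unstratified[bid],
                              bootstrap_id=bid, scheme=s)
            for s in ["A", "B"]
        }
        comp = compose_best(preds, strata, ms, BEST_RSE,
                            bootstrap_id=bid, unstratified_raster=un)
        assert np.all(comp.log_raster.values == 5.0)
        assert np.all(comp.provenance == 0)

    def test_unknown_metric_rejected(self, spec, cov):
        strata, ms, preds, un, bid = _two_scheme_setup(spec, cov)
        with pytest.raises(ValueError):
            compose_best(preds, strata, ms, "best_guess",
                         bootstrap_id=bid, unstratified_raster=un)


class _OnePointPlan:
    """Minimal bootstrap plan stub: one bootstrap, explicit indices."""

    def __init__(self, train, test, n):
        self._train, self._test, self._n = np.asarray(train), np.asarray(test), n

    @property
    def bootstrap_ids(self):
        return [(0, 0)]

    def train_index(self, bid):
        return self._train

    def test_index(self, bid, file_col):
        return self._test


class TestEvaluate:
    def _points(self, y):
        n = len(y)
        return pd.DataFrame(
            {"file": 0, "y": y, "polygon_id": [f"p{i}" for i in range(n)],
             "cov_c": np.zeros(n), "stratum_A": 1}
        )

    def _modelset(self, intercept):
        ms = ModelSet(cov_names=["c"], schemes=["A"])
        ms.models[(0, 0, "A", 1)] = _model(intercept, "A")
        ms.unstratified[(0, 0)] = _model(intercept, UNSTRATIFIED, UNSTRATIFIED)
        return ms

    def test_perfect_predictions(self):
        pts = self._points([1.0, 1.0, 1.0])
        rep = evaluate(pts, _OnePointPlan([0], [1, 2], 3), self._modelset(1.0))
        pooled = rep[rep.bootstrap == "pooled"].set_index("variant")
        assert pooled.loc["A", "rmse"] == 0.0

    def test_rmse_arithmetic(self):
        # obs (0,1,2) vs constant prediction 1 -> RMSE = sqrt(2/3)
        pts = self._points([0.0, 1.0, 2.0])
        rep = evaluate(pts, _OnePointPlan([0], [0, 1, 2], 3), self._modelset(1.0))
        pooled = rep[rep.bootstrap == "pooled"].set_index("variant")
        assert pooled.loc["A", "rmse"] == pytest.approx(np.sqrt(2 / 3))

    def test_constant_predictions_flag_r_undefined(self):
        pts = self._points([0.0, 1.0, 2.0])
        rep = evaluate(pts, _OnePointPlan([0], [0, 1, 2], 3), self._modelset(1.0))
        pooled = rep[rep.bootstrap == "pooled"].set_index("variant")
        assert np.isnan(pooled.loc["A", "r"])
        assert pooled.loc["A", "rmse"] >= 0


class TestSelectFinal:
    def _report(self, comp_rse, single_a, comp_r2=None, unstrat=2.0):
        rows = [
            (COMPOSITE_RSE, "pooled", 0.9, comp_rse, 100),
            (COMPOSITE_R2, "pooled", 0.9, comp_r2 if comp_r2 is not None else comp_rse, 100),
            ("A", "pooled", 0.9, single_a, 100),
            (VARIANT_UNSTRATIFIED, "pooled", 0.5, unstrat, 100),
        ]
        return pd.DataFrame(rows, columns=["variant", "bootstrap", "r", "rmse", "n"])

    def test_composite_taken_when_improvement_exceeds_margin(self):
        # 0.50 vs 0.51 is a 1.96% improvement over a 1% margin
        assert select_final(self._report(0.50, 0.51), 0.01, ["A"]) == COMPOSITE_RSE

    def test_tie_prefers_single_scheme(self):
        assert select_final(self._report(0.500, 0.500), 0.01, ["A"]) == "A"

    def test_worse_composite_rejected(self):
        assert select_final(self._report(0.60, 0.50), 0.01, ["A"]) == "A"


class TestEnsemble:
    def test_consensus_pixel(self, spec):
        mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
        r = [Raster(spec, np.full(spec.shape, 2.0)) for _ in range(3)]
        ens = ensemble_aggregate(r, mask)
        assert np.all(ens.mean_log.values == 2.0)
        assert np.all(ens.sd_log.values == 0.0)
        assert np.all(ens.density.values == pytest.approx(99.0))

    def test_negative_mean_log_clips_to_zero_density(self, spec):
        mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
        r = [Raster(spec, np.full(spec.shape, -0.1)) for _ in range(2)]
        ens = ensemble_aggregate(r, mask)
        assert np.all(ens.density.values == 0.0)

    def test_unsuitable_pixels_zeroed(self, spec):
        cat = np.full(spec.shape, float(SUITABLE))
        cat[0, :] = UNSUITABLE_ENV
        mask = SuitabilityMask(Raster(spec, cat))
        r = [Raster(spec, np.full(spec.shape, 1.0)) for _ in range(2)]
        ens = ensemble_aggregate(r, mask)
        assert np.all(ens.density.values[0, :] == 0.0)
        assert np.all(ens.density.values[1:, :] == pytest.approx(9.0))

    def test_mean_invariant_to_bootstrap_order(self, spec):
        rng = np.random.default_rng(0)
        mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
        rs = [Raster(spec, rng.random(spec.shape)) for _ in range(4)]
        e1 = ensemble_aggregate(rs, mask)
        e2 = ensemble_aggregate(rs[::-1], mask)
        np.testing.assert_allclose(e1.mean_log.values, e2.mean_log.values)
        np.testing.assert_allclose(e1.sd_log.values, e2.sd_log.values)

    def test_duplicating_all_bootstraps_keeps_sd(self, spec):
        rng = np.random.default_rng(1)
        mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
        rs = [Raster(spec, rng.random(spec.shape)) for _ in range(3)]
        e1 = ensemble_aggregate(rs, mask)
        e2 = ensemble_aggregate(rs + rs, mask)
        np.testing.assert_allclose(e1.sd_log.values, e2.sd_log.values)

    def test_single_bootstrap_rejected(self, spec):
        mask = SuitabilityMask(Raster(spec, np.full(spec.shape, float(SUITABLE))))
        with pytest.raises(ValueError):
            ensemble_aggregate([Raster(spec, np.zeros(spec.shape))], mask)
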