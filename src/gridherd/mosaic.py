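"""Raster prediction, per-bootstrap composites, evaluation and ensembling.

For each bootstrap a predicted log10-density raster is produced per
stratification scheme (pixels in strata without a model fall back to the
unstratified fit). A composite then picks, pixel by pixel, the scheme
whose covering stratum model has the best R-squared or the best residual
standard error; a provenance raster records which scheme contributed each
pixel (0 = unstratified fallback). Variants are scored on the held-out
test points by Pearson r and RMSE on the log scale, the final variant is
chosen by parsimony, and the 25 per-bootstrap rasters of that variant are
averaged into mean/SD log-density surfaces and a back-transformed density
surface with zero density on unsuitable land.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geodata import Raster, _require_same_grid
from .masking import SuitabilityMask
from .regression import ModelSet, StratumModel, UNSTRATIFIED
from .sampling import inverse_transform

logger = logging.getLogger(__name__)

BEST_R2 = "best_r2"
BEST_RSE = "best_rse"

COMPOSITE_R2 = "composite_r2"
COMPOSITE_RSE = "composite_rse"
VARIANT_UNSTRATIFIED = "unstratified"

#: density below which a coefficient of variation is not reported
CV_MEAN_EPS = 1e-6


@dataclass
class SchemePrediction:
    """Predicted log10 densities of one scheme in one bootstrap."""

    bootstrap_id: tuple
    scheme: str
    log_raster: Raster
    fallback: np.ndarray  # True where the unstratified model filled in


@dataclass
class CompositeResult:
    """Best-scheme-per-pixel composite of one bootstrap."""

    bootstrap_id: tuple
    metric: str
    log_raster: Raster
    provenance: np.ndarray  # scheme index + 1; 0 = unstratified


@dataclass
class EnsembleResult:
    """Bootstrap-ensemble summary surfaces."""

    mean_log: Raster
    sd_log: Raster
    density: Raster          # head km**-2, zero on unsuitable land
    cv: Raster               # of back-transformed per-bootstrap densities
    provenance_mode: Raster  # modal provenance code across bootstraps


def _covariate_matrix(covariates: dict[str, Raster], cov_names: Sequence[str]):
    first = covariates[cov_names[0]]
    n = first.spec.n_rows * first.spec.n_cols
    X = np.empty((n, len(cov_names)))
    valid = np.ones(n, dtype=bool)
    for j, name in enumerate(cov_names):
        r = covariates[name]
        X[:, j] = r.values.ravel()
        valid &= r.values.ravel() != r.spec.nodata
    return X, valid


def predict_scheme(
    models: dict[int, StratumModel],
    covariates: dict[str, Raster],
    cov_names: Sequence[str],
    stratum_raster: Raster,
    fallback: StratumModel,
    *,
    bootstrap_id: tuple = (0, 0),
    scheme: str = "scheme",
) -> SchemePrediction:
    """Apply each stratum's model to its pixels; model-less strata get the
    unstratified fallback and are flagged. Covariate nodata -> nodata."""
    spec = stratum_raster.spec
    for r in covariates.values():
        _require_same_grid(stratum_raster, r)
    X, valid = _covariate_matrix(covariates, cov_names)
    cov_index = {c: j for j, c in enumerate(cov_names)}
    codes = stratum_raster.values.ravel()
    out = np.full(X.shape[0], spec.nodata)
    is_fallback = np.zeros(X.shape[0], dtype=bool)
    for code in np.unique(codes[valid]).astype(int):
        sel = valid & (codes == code)
        model = models.get(code)
        if model is None:
            model = fallback
            is_fallback[sel] = True
        out[sel] = model.predict(X[sel], cov_index)
    return SchemePrediction(
        bootstrap_id, scheme, Raster(spec, out.reshape(spec.shape)),
        is_fallback.reshape(spec.shape),
    )


def _metric_value(model: StratumModel, metric: str) -> float:
    if metric == BEST_R2:
        return model.r2
    if metric == BEST_RSE:
        return model.rse
    raise ValueError(f"unknown metric {metric!r}")


def compose_best(
    predictions: dict[str, SchemePrediction],
    stratum_rasters: dict[str, Raster],
    model_set: ModelSet,
    metric: str,
    *,
    bootstrap_id: tuple,
    unstratified_raster: Raster,
    scheme_order: Sequence[str] | None = None,
) -> CompositeResult:
    """Per pixel, keep the scheme whose covering stratum model is best by
    the chosen metric; only real (non-fallback) models compete. Pixels no
    scheme covers take the unstratified prediction with provenance 0.
    Ties go to the scheme earliest in ``scheme_order``."""
    if metric not in (BEST_R2, BEST_RSE):
        raise ValueError(f"unknown metric {metric!r}")
    order = list(scheme_order or model_set.schemes)
    spec = unstratified_raster.spec
    best_metric = np.full(spec.shape, np.nan)
    out = unstratified_raster.values.copy()
    provenance = np.zeros(spec.shape, dtype=int)
    sign = 1.0 if metric == BEST_R2 else -1.0  # maximise signed metric
    for si, scheme in enumerate(order):
        pred = predictions[scheme]
        codes = stratum_rasters[scheme].values
        stratum_models = model_set.stratum_models(bootstrap_id, scheme)
        mvals = np.full(spec.shape, np.nan)
        for code, model in stratum_models.items():
            mvals[codes == code] = sign * _metric_value(model, metric)
        mvals[pred.fallback] = np.nan
        mvals[pred.log_raster.nodata_mask] = np.nan
        better = ~np.isnan(mvals) & (np.isnan(best_metric) | (mvals > best_metric))
        out[better] = pred.log_raster.values[better]
        provenance[better] = si + 1
        best_metric[better] = mvals[better]
    return CompositeResult(bootstrap_id, metric, Raster(spec, out), provenance)


def predict_points(
    points: pd.DataFrame,
    index: np.ndarray,
    model_set: ModelSet,
    bid: tuple,
) -> pd.DataFrame:
    """Predicted y at the given point rows for every variant.

    Variants: the unstratified model, each scheme, and the two composites
    (per point, the best real stratum model by R-squared / by RSE among
    schemes covering the point's stratum)."""
    X = points[[f"cov_{c}" for c in model_set.cov_names]].to_numpy()[index]
    cov_index = {c: j for j, c in enumerate(model_set.cov_names)}
    out = pd.DataFrame(index=index)
    fallback = model_set.unstratified[bid]
    y_fb = fallback.predict(X, cov_index)
    out[VARIANT_UNSTRATIFIED] = y_fb
    per_scheme: dict[str, np.ndarray] = {}
    scheme_metric: dict[str, dict[str, np.ndarray]] = {BEST_R2: {}, BEST_RSE: {}}
    for scheme in model_set.schemes:
        codes = points[f"stratum_{scheme}"].to_numpy()[index]
        models = model_set.stratum_models(bid, scheme)
        pred = y_fb.copy()
        mr2 = np.full(index.size, np.nan)
        mrse = np.full(index.size, np.nan)
        for code, model in models.items():
            sel = codes == code
            pred[sel] = model.predict(X[sel], cov_index)
            mr2[sel] = model.r2
            mrse[sel] = model.rse
        per_scheme[scheme] = pred
        scheme_metric[BEST_R2][scheme] = mr2
        scheme_metric[BEST_RSE][scheme] = mrse
        out[scheme] = pred
    for metric, variant in ((BEST_R2, COMPOSITE_R2), (BEST_RSE, COMPOSITE_RSE)):
        sign = 1.0 if metric == BEST_R2 else -1.0
        best = np.full(index.size, np.nan)
        comp = y_fb.copy()
        for scheme in model_set.schemes:
            mv = sign * scheme_metric[metric][scheme]
            better = ~np.isnan(mv) & (np.isnan(best) | (mv > best))
            comp[better] = per_scheme[scheme][better]
            best[better] = mv[better]
        out[variant] = comp
    return out


def _pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    if obs.size < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")  # undefined, flagged rather than erroring
    return float(np.corrcoef(obs, pred)[0, 1])


def evaluate(
    points: pd.DataFrame,
    plan,
    model_set: ModelSet,
) -> pd.DataFrame:
    """Pearson r and RMSE (log scale) of every variant on the held-out
    test points, per bootstrap plus pooled rows (bootstrap = 'pooled')."""
    file_col = points["file"].to_numpy()
    y = points["y"].to_numpy()
    rows = []
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for bid in plan.bootstrap_ids:
        te = plan.test_index(bid, file_col)
        if te.size == 0:
            raise ValueError(f"bootstrap {bid}: empty test set")
        preds = predict_points(points, te, model_set, bid)
        obs = y[te]
        for variant in preds.columns:
            p = preds[variant].to_numpy()
            rows.append(
                (variant, f"{bid[0]}:{bid[1]}", _pearson(obs, p),
                 float(np.sqrt(np.mean((obs - p) ** 2))), te.size)
            )
            pooled.setdefault(variant, []).append((obs, p))
    for variant, chunks in pooled.items():
        obs = np.concatenate([o for o, _ in chunks])
        p = np.concatenate([q for _, q in chunks])
        rows.append(
            (variant, "pooled", _pearson(obs, p),
             float(np.sqrt(np.mean((obs - p) ** 2))), obs.size)
        )
    return pd.DataFrame(rows, columns=["variant", "bootstrap", "r", "rmse", "n"])


def select_final(
    report: pd.DataFrame,
    margin: float = 0.01,
    schemes: Sequence[str] | None = None,
) -> str:
    """Choose the final variant by parsimony.

    The better composite (preferring best-RSE on ties) is taken only when
    its pooled RMSE improves on the best single scheme's by more than the
    relative ``margin``; otherwise the best single scheme is kept."""
    pooled = report[report["bootstrap"] == "pooled"].set_index("variant")["rmse"]
    if schemes is None:
        schemes = [
            v for v in pooled.index
            if v not in (COMPOSITE_R2, COMPOSITE_RSE, VARIANT_UNSTRATIFIED)
        ]
    single = pooled.loc[list(schemes)]
    best_single = single.idxmin()
    comp = COMPOSITE_RSE if pooled[COMPOSITE_RSE] <= pooled[COMPOSITE_R2] else COMPOSITE_R2
    best_rmse = single[best_single]
    improvement = (best_rmse - pooled[comp]) / best_rmse if best_rmse > 0 else 0.0
    ranking = pooled.sort_values()
    logger.info("variant ranking by pooled RMSE:\n%s", ranking.to_string())
    if improvement > margin:
        return comp
    return str(best_single)


def ensemble_aggregate(
    log_rasters: Sequence[Raster],
    mask: SuitabilityMask,
    provenances: Sequence[np.ndarray] | None = None,
) -> EnsembleResult:
    """Average the chosen variant's per-bootstrap log10 predictions.

    Mean and SD are per pixel over bootstraps; the density surface is
    max(0, 10**mean - 1) with both unsuitable categories forced to zero;
    the CV is SD/mean of the back-transformed per-bootstrap densities,
    undefined (nan) where the mean density is negligible."""
    if len(log_rasters) < 2:
        raise ValueError("need at least two bootstraps to aggregate")
    spec = log_rasters[0].spec
    for r in log_rasters:
        _require_same_grid(log_rasters[0], r)
    _require_same_grid(log_rasters[0], mask.raster)
    stack = np.stack([r.values for r in log_rasters])
    valid = np.all(stack != spec.nodata, axis=0)
    mean = np.where(valid, stack.mean(axis=0), spec.nodata)
    sd = np.where(valid, stack.std(axis=0, ddof=0), spec.nodata)
    density = np.where(valid, inverse_transform(mean), spec.nodata)
    density[mask.unsuitable & valid] = 0.0
    dstack = inverse_transform(stack)
    dmean = dstack.mean(axis=0)
    dsd = dstack.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(valid & (dmean >= CV_MEAN_EPS), dsd / dmean, np.nan)
    cv = np.where(np.isnan(cv), spec.nodata, cv)
    if provenances is not None:
        pstack = np.stack(provenances)
        # modal code: count occurrences of each code per pixel
        codes = np.unique(pstack)
        counts = np.stack([(pstack == c).sum(axis=0) for c in codes])
        mode = codes[np.argmax(counts, axis=0)].astype(float)
    else:
        mode = np.zeros(spec.shape)
    return EnsembleResult(
        mean_log=Raster(spec, mean),
        sd_log=Raster(spec, sd),
        density=Raster(spec, density),
        cv=Raster(spec, cv),
        provenance_mode=Raster(spec, mode),
    )
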