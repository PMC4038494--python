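"""End-to-end orchestration: sample -> fit -> predict -> ensemble.

Ties the sampling, regression and mosaic stages together for a single
tile: draws the bootstrap point files from the training polygons, fits all
stratum and fallback models, builds per-bootstrap scheme predictions and
composites, scores every variant on the held-out points, picks the final
variant by parsimony, and aggregates the bootstrap ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .geodata import AdminPolygonLayer, Raster, ZoneRaster, rasterize_polygons
from .masking import SuitabilityMask
from .mosaic import (
    BEST_R2,
    BEST_RSE,
    COMPOSITE_R2,
    COMPOSITE_RSE,
    VARIANT_UNSTRATIFIED,
    CompositeResult,
    EnsembleResult,
    SchemePrediction,
    compose_best,
    ensemble_aggregate,
    evaluate,
    predict_scheme,
    select_final,
)
from .regression import ModelSet, fit_all
from .sampling import assign_bootstraps, build_sample_files, extract_point_data

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    points: pd.DataFrame
    model_set: ModelSet
    report: pd.DataFrame
    chosen_variant: str
    ensemble: EnsembleResult


def run_pipeline(
    layer: AdminPolygonLayer,
    covariates: dict[str, Raster],
    strata: dict[str, Raster],
    mask: SuitabilityMask,
    areas: Raster,
    config: RunConfig | None = None,
    seed: int | None = None,
    *,
    zones: ZoneRaster | None = None,
) -> PipelineResult:
    """Run the full downscaling chain on one tile."""
    cfg = config or RunConfig()
    if seed is None:
        seed = cfg.seed
    cov_names = sorted(covariates)
    scheme_names = sorted(strata)
    if zones is None:
        zones = rasterize_polygons(layer, mask.spec)

    pts = build_sample_files(
        layer, mask, areas, cfg.sample_density, cfg.n_files, seed, zones=zones
    )
    pts = extract_point_data(pts, covariates, strata)
    plan = assign_bootstraps(pts, cfg.n_selections, cfg.train_fraction, seed)

    model_set = fit_all(
        pts, plan, scheme_names, cov_names,
        min_unique=cfg.min_unique,
        obs_per_term=cfg.obs_per_term,
        aic_rel_threshold=cfg.aic_rel_threshold,
        llr_threshold=cfg.llr_threshold,
    )

    report = evaluate(pts, plan, model_set)
    chosen = select_final(report, cfg.parsimony_margin, scheme_names)
    logger.info("final variant: %s", chosen)

    cov_index = {c: j for j, c in enumerate(cov_names)}
    rasters: list[Raster] = []
    provenances: list[np.ndarray] = []
    for bid in model_set.bootstrap_ids:
        fallback = model_set.unstratified[bid]
        preds: dict[str, SchemePrediction] = {}
        for scheme in scheme_names:
            preds[scheme] = predict_scheme(
                model_set.stratum_models(bid, scheme),
                covariates, cov_names, strata[scheme], fallback,
                bootstrap_id=bid, scheme=scheme,
            )
        if chosen == VARIANT_UNSTRATIFIED:
            uy = fallback.predict(
                np.column_stack([covariates[c].values.ravel() for c in cov_names]),
                cov_index,
            ).reshape(mask.spec.shape)
            rasters.append(Raster(mask.spec, uy))
            provenances.append(np.zeros(mask.spec.shape, dtype=int))
        elif chosen in (COMPOSITE_R2, COMPOSITE_RSE):
            metric = BEST_R2 if chosen == COMPOSITE_R2 else BEST_RSE
            # the unstratified surface every composite falls back to
            un = predict_scheme(
                {}, covariates, cov_names, strata[scheme_names[0]], fallback,
                bootstrap_id=bid, scheme=VARIANT_UNSTRATIFIED,
            ).log_raster
            comp = compose_best(
                preds, strata, model_set, metric,
                bootstrap_id=bid, unstratified_raster=un,
                scheme_order=scheme_names,
            )
            rasters.append(comp.log_raster)
            provenances.append(comp.provenance)
        else:  # a single stratification scheme
            sp = preds[chosen]
            rasters.append(sp.log_raster)
            code = scheme_names.index(chosen) + 1
            prov = np.where(sp.fallback, 0, code)
            provenances.append(prov)

    ensemble = ensemble_aggregate(rasters, mask, provenances)
    return PipelineResult(pts, model_set, report, chosen, ensemble)
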