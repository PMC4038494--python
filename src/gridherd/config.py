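"""Run configuration: every tunable threshold of the modelling system.

Defaults are the production values of the downscaling procedure: a 4,750 m
elevation ceiling, a 40% slope limit, strictly protected IUCN categories
(Ia, Ib, II, III) masked, 30 sample points per 10,000 km**2, 75/25
train/test splits over 5 point files x 5 selections, a 30-unique-polygon
floor per stratum, an n/15 entered-variable cap, a 1% relative-AIC and a
2*log-likelihood-ratio >= 6 halting rule, and a 1% parsimony margin for
preferring a composite over a single stratification.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .masking import (
    DEFAULT_MAX_ELEVATION_M,
    DEFAULT_MAX_SLOPE_PCT,
    DEFAULT_PROTECTED_CODES,
    DEFAULT_SNOWICE_CODES,
    DEFAULT_URBAN_CODES,
)
from .mosaic import BEST_RSE
from .regression import (
    DEFAULT_AIC_REL_THRESHOLD,
    DEFAULT_LLR_THRESHOLD,
    DEFAULT_MIN_UNIQUE,
    DEFAULT_OBS_PER_TERM,
)
from .sampling import DEFAULT_SAMPLE_DENSITY


@dataclass
class RunConfig:
    """All numeric constants of a modelling run, with production defaults."""

    species: str = "cattle"
    seed: int | None = None

    # masking
    max_elevation_m: float = DEFAULT_MAX_ELEVATION_M
    max_slope_pct: float = DEFAULT_MAX_SLOPE_PCT
    urban_codes: tuple[int, ...] = DEFAULT_URBAN_CODES
    snowice_codes: tuple[int, ...] = DEFAULT_SNOWICE_CODES
    protected_codes: tuple[int, ...] = DEFAULT_PROTECTED_CODES

    # sampling / bootstraps
    sample_density: float = DEFAULT_SAMPLE_DENSITY  # points per 10,000 km2
    n_files: int = 5
    n_selections: int = 5
    train_fraction: float = 0.75

    # regression
    min_unique: int = DEFAULT_MIN_UNIQUE
    obs_per_term: int = DEFAULT_OBS_PER_TERM
    aic_rel_threshold: float = DEFAULT_AIC_REL_THRESHOLD
    llr_threshold: float = DEFAULT_LLR_THRESHOLD

    # mosaic
    metric: str = BEST_RSE
    parsimony_margin: float = 0.01

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("urban_codes", "snowice_codes", "protected_codes"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key: {sorted(unknown)[0]}")
        kw = dict(d)
        for k in ("urban_codes", "snowice_codes", "protected_codes"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)
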