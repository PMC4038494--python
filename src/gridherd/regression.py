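"""Paired linear+quadratic forward-stepwise regression per stratum.

Within each stratum of each stratification scheme (and once without
stratification, as the fallback), an ordinary-least-squares model of
log10(density + 1) is grown forward from the intercept. Candidate
covariates enter in pairs -- each variable together with its square -- to
capture non-linear responses; at every step the pair giving the largest
AIC reduction is the candidate, and it is accepted only while

* the relative AIC drop is at least 1%,
* twice the log-likelihood-ratio of the step is at least 6
  (a chi-square test on 2 df at p ~ 0.05), and
* the entered-term count stays within n_points / 15,

all three conjunctively; the fit halts at the first rejection. A stratum
is modelled at all only if its training points come from at least 30
distinct polygons ("unique observations": points sharing a polygon share
the dependent value).

Covariates are standardised within the fitting set before squaring to tame
the collinearity of quadratic terms; predictions are invariant to this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNSTRATIFIED = "__unstratified__"

DEFAULT_MIN_UNIQUE = 30
DEFAULT_OBS_PER_TERM = 15
DEFAULT_AIC_REL_THRESHOLD = 0.01
DEFAULT_LLR_THRESHOLD = 6.0

_RSS_FLOOR = 1e-300


def count_unique_observations(polygon_ids: Sequence) -> int:
    """Number of distinct polygons represented among the points."""
    return len(set(polygon_ids))


def gaussian_aic(n: int, rss: float, n_slopes: int) -> float:
    """AIC = n ln(RSS/n) + 2(k+1) with k fitted slopes plus the intercept."""
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * (n_slopes + 1)


def gaussian_loglik(n: int, rss: float) -> float:
    """Maximised Gaussian log-likelihood of an OLS fit."""
    return -0.5 * n * (math.log(2 * math.pi * max(rss, _RSS_FLOOR) / n) + 1.0)


def halting_pvalue(threshold: float = DEFAULT_LLR_THRESHOLD, df: int = 2) -> float:
    """p-value of the likelihood-ratio halting threshold on ``df`` degrees
    of freedom (chi-square survival function)."""
    return float(stats.chi2.sf(threshold, df))


@dataclass
class StratumModel:
    """A fitted stepwise model for one stratum (or the unstratified pool)."""

    scheme: str
    stratum: int | str
    terms: list[str]                 # covariate names in entry order
    means: np.ndarray                # standardisation per entered covariate
    sds: np.ndarray
    beta: np.ndarray                 # intercept, then (lin, quad) per term
    n_points: int
    n_unique: int
    aic_trace: list[float]
    r2: float
    rse: float
    loglik: float

    @property
    def n_terms_entered(self) -> int:
        """Entered variables counting linear and quadratic separately."""
        return 2 * len(self.terms)

    def design(self, X: np.ndarray, cov_index: dict[str, int]) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        for j, name in enumerate(self.terms):
            z = (X[:, cov_index[name]] - self.means[j]) / self.sds[j]
            cols += [z, z * z]
        return np.column_stack(cols)

    def predict(self, X: np.ndarray, cov_index: dict[str, int]) -> np.ndarray:
        """Predicted log10-density for rows of covariate matrix ``X``."""
        return self.design(X, cov_index) @ self.beta

    def raw_coefficients(self) -> dict[str, float]:
        """Coefficients on the un-standardised covariate scale."""
        out = {"intercept": float(self.beta[0])}
        for j, name in enumerate(self.terms):
            b_lin = self.beta[1 + 2 * j]
            b_quad = self.beta[2 + 2 * j]
            m, s = self.means[j], self.sds[j]
            # y = b0 + bl (x-m)/s + bq ((x-m)/s)^2
            out[name] = float(b_lin / s - 2 * b_quad * m / s**2)
            out[f"{name}^2"] = float(b_quad / s**2)
            out["intercept"] += float(-b_lin * m / s + b_quad * m**2 / s**2)
        return out

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "stratum": self.stratum,
            "terms": self.terms,
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "beta": list(map(float, self.beta)),
            "n_points": self.n_points,
            "n_unique": self.n_unique,
            "aic_trace": list(map(float, self.aic_trace)),
            "r2": self.r2,
            "rse": self.rse,
            "loglik": self.loglik,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StratumModel":
        return cls(
            scheme=d["scheme"],
            stratum=d["stratum"],
            terms=list(d["terms"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            n_points=int(d["n_points"]),
            n_unique=int(d["n_unique"]),
            aic_trace=list(d["aic_trace"]),
            r2=float(d["r2"]),
            rse=float(d["rse"]),
            loglik=float(d["loglik"]),
        )


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Least-squares fit; None when the design is rank-deficient."""
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def stepwise_fit(
    y: np.ndarray,
    X: np.ndarray,
    cov_names: Sequence[str],
    polygon_ids: Sequence,
    *,
    scheme: str = UNSTRATIFIED,
    stratum: int | str = UNSTRATIFIED,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    obs_per_term: int = DEFAULT_OBS_PER_TERM,
    aic_rel_threshold: float = DEFAULT_AIC_REL_THRESHOLD,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
) -> StratumModel | None:
    """Fit the paired-stepwise model; ``None`` means the stratum is refused
    for having fewer than ``min_unique`` unique observations."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    n_unique = count_unique_observations(polygon_ids)
    if n_unique < min_unique:
        return None

    max_terms = n // obs_per_term
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    usable = sds > 0
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - means[usable]) / sds[usable]

    ones = np.ones((n, 1))
    fit0 = _ols(ones, y)
    assert fit0 is not None
    beta, rss = fit0
    tss = rss  # intercept-only RSS is the total sum of squares
    design = ones
    entered: list[int] = []
    aic = gaussian_aic(n, rss, 0)
    trace = [aic]

    while True:
        # an (effectively) exact fit cannot be improved; ratios of
        # floating-point residual noise must not drive further steps
        if rss <= 1e-12 * max(tss, 1.0):
            break
        best = None  # (aic, j, beta, rss, design)
        for j in range(X.shape[1]):
            if j in entered or not usable[j]:
                continue
            cand = np.column_stack([design, Z[:, j], Z[:, j] ** 2])
            fit = _ols(cand, y)
            if fit is None:
                logger.warning("rank-deficient candidate %s skipped", cov_names[j])
                continue
            b, r = fit
            a = gaussian_aic(n, r, cand.shape[1] - 1)
            if best is None or a < best[0]:
                best = (a, j, b, r, cand)
        if best is None:
            break
        a_new, j, b_new, rss_new, design_new = best
        if 2 * len(entered) + 2 > max_terms:
            break
        if aic != 0.0:
            if (aic - a_new) / abs(aic) < aic_rel_threshold:
                break
        llr2 = n * math.log(max(rss, _RSS_FLOOR) / max(rss_new, _RSS_FLOOR))
        if llr2 < llr_threshold:
            break
        entered.append(j)
        beta, rss, design, aic = b_new, rss_new, design_new, a_new
        trace.append(aic)

    k = design.shape[1] - 1
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - k - 1
    rse = math.sqrt(rss / dof) if dof > 0 else float("nan")
    return StratumModel(
        scheme=scheme,
        stratum=stratum,
        terms=[cov_names[j] for j in entered],
        means=means[entered] if entered else np.empty(0),
        sds=sds[entered] if entered else np.empty(0),
        beta=beta,
        n_points=n,
        n_unique=n_unique,
        aic_trace=trace,
        r2=r2,
        rse=rse,
        loglik=gaussian_loglik(n, rss),
    )


@dataclass
class ModelSet:
    """All fitted models of a run, keyed by bootstrap, scheme and stratum."""

    cov_names: list[str]
    schemes: list[str]
    models: dict[tuple, StratumModel] = field(default_factory=dict)
    unstratified: dict[tuple, StratumModel] = field(default_factory=dict)
    refused: list[tuple] = field(default_factory=list)  # (bid, scheme, stratum, n_unique)

    def stratum_models(self, bid: tuple, scheme: str) -> dict[int, StratumModel]:
        return {
            key[3]: m
            for key, m in self.models.items()
            if key[0] == bid[0] and key[1] == bid[1] and key[2] == scheme
        }

    @property
    def bootstrap_ids(self) -> list[tuple[int, int]]:
        return sorted(self.unstratified)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (f, s, scheme, stratum), m in sorted(self.models.items(), key=str):
            rows.append((f, s, scheme, stratum, m.n_points, m.n_unique,
                         len(m.terms), m.r2, m.rse))
        for (f, s), m in sorted(self.unstratified.items()):
            rows.append((f, s, UNSTRATIFIED, UNSTRATIFIED, m.n_points,
                         m.n_unique, len(m.terms), m.r2, m.rse))
        return pd.DataFrame(
            rows,
            columns=["file", "selection", "scheme", "stratum", "n_points",
                     "n_unique", "n_pairs", "r2", "rse"],
        )

    def to_json(self, path) -> None:
        import json

        payload = {
            "cov_names": self.cov_names,
            "schemes": self.schemes,
            "models": [
                {"file": k[0], "selection": k[1], **m.to_dict()}
                for k, m in sorted(self.models.items(), key=str)
            ],
            "unstratified": [
                {"file": k[0], "selection": k[1], **m.to_dict()}
                for k, m in sorted(self.unstratified.items())
            ],
            "refused": [list(r) for r in self.refused],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        ms = cls(cov_names=payload["cov_names"], schemes=payload["schemes"])
        for rec in payload["models"]:
            m = StratumModel.from_dict(rec)
            ms.models[(rec["file"], rec["selection"], m.scheme, m.stratum)] = m
        for rec in payload["unstratified"]:
            m = StratumModel.from_dict(rec)
            ms.unstratified[(rec["file"], rec["selection"])] = m
        ms.refused = [tuple(r) for r in payload["refused"]]
        return ms


def fit_all(
    points: pd.DataFrame,
    plan,
    schemes: Sequence[str],
    cov_names: Sequence[str],
    *,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    obs_per_term: int = DEFAULT_OBS_PER_TERM,
    aic_rel_threshold: float = DEFAULT_AIC_REL_THRESHOLD,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
) -> ModelSet:
    """Fit every (bootstrap, scheme, stratum) with enough unique
    observations, plus one unstratified fallback model per bootstrap.

    Raises ``RuntimeError`` if the unstratified pool itself is refused --
    without a fallback no pixel could be predicted.
    """
    kw = dict(
        obs_per_term=obs_per_term,
        aic_rel_threshold=aic_rel_threshold,
        llr_threshold=llr_threshold,
    )
    X_all = points[[f"cov_{c}" for c in cov_names]].to_numpy()
    y_all = points["y"].to_numpy()
    pid_all = points["polygon_id"].to_numpy()
    out = ModelSet(cov_names=list(cov_names), schemes=list(schemes))
    for bid in plan.bootstrap_ids:
        tr = plan.train_index(bid)
        m = stepwise_fit(
            y_all[tr], X_all[tr], list(cov_names), pid_all[tr],
            scheme=UNSTRATIFIED, stratum=UNSTRATIFIED,
            min_unique=min_unique, **kw,
        )
        if m is None:
            raise RuntimeError(
                f"bootstrap {bid}: unstratified pool has fewer than "
                f"{min_unique} unique polygons; cannot proceed"
            )
        out.unstratified[bid] = m
        for scheme in schemes:
            codes = points[f"stratum_{scheme}"].to_numpy()[tr]
            for code in np.unique(codes):
                sel = tr[codes == code]
                sm = stepwise_fit(
                    y_all[sel], X_all[sel], list(cov_names), pid_all[sel],
                    scheme=scheme, stratum=int(code),
                    min_unique=min_unique, **kw,
                )
                if sm is None:
                    out.refused.append(
                        (bid, scheme, int(code), count_unique_observations(pid_all[sel]))
                    )
                else:
                    out.models[(bid[0], bid[1], scheme, int(code))] = sm
    return out
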