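"""Independent reference implementation of the paired-stepwise selection.

Used only as a cross-check: exhaustive enumeration of candidate pairs via
statsmodels OLS, with AIC and the likelihood-ratio computed directly from
residual sums of squares. Shares no code with the package implementation.
"""

import math

import numpy as np
import statsmodels.api as sm


def oracle_stepwise(y, X, min_unique, polygon_ids, obs_per_term=15,
                    aic_rel=0.01, llr=6.0):
    """Entered covariate indices, in order; None when refused."""
    n = len(y)
    if len(set(polygon_ids)) < min_unique:
        return None
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    design = np.ones((n, 1))
    rss_prev = float(sm.OLS(y, design).fit().ssr)
    tss = rss_prev
    aic_prev = n * math.log(rss_prev / n) + 2
    entered = []
    while True:
        if rss_prev <= 1e-12 * max(tss, 1.0):
            break
        cands = []
        for j in range(X.shape[1]):
            if j in entered:
                continue
            d = np.column_stack([design, Z[:, j], Z[:, j] ** 2])
            res = sm.OLS(y, d).fit()
            rss = float(res.ssr)
            aic = n * math.log(max(rss, 1e-300) / n) + 2 * d.shape[1]
            cands.append((aic, j, rss, d))
        if not cands:
            break
        aic_new, j, rss_new, d_new = min(cands, key=lambda t: t[0])
        if 2 * len(entered) + 2 > n // obs_per_term:
            break
        if aic_prev != 0 and (aic_prev - aic_new) / abs(aic_prev) < aic_rel:
            break
        if n * math.log(max(rss_prev, 1e-300) / max(rss_new, 1e-300)) < llr:
            break
        entered.append(j)
        design, rss_prev, aic_prev = d_new, rss_new, aic_new
    return entered
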