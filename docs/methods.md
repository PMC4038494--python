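# Methods

## The problem

Livestock census data arrive as totals per administrative polygon, at
heterogeneous levels (national to sub-district), with gaps marked by a
−9999 sentinel. `gridherd` disaggregates those totals onto a geographic
grid using environmental covariates, under the constraint that the gridded
surface, integrated back over each reporting unit, reproduces the reported
total. All layers share one unprojected WGS84 grid; pixel areas follow the
spherical band formula A = R² Δλ (sin φ_top − sin φ_bot) with the authalic
radius R = 6371.0088 km (the sphere is used throughout: the area model
stays closed-form and testable, and no source states an ellipsoid).

## Suitability and the dependent variable

A three-way mask partitions land:

* `UNSUITABLE_ENV` — elevation > 4,750 m, slope > 40 %, urban or permanent
  snow/ice land cover. Modelled as *true zeros*: sample points falling
  here keep y = 0, and final surfaces are zeroed here.
* `UNSUITABLE_LEG` — strictly protected areas (IUCN Ia, Ib, II, III by
  default). These are *excluded* (no sample points, zeroed in output)
  rather than asserted to be empty.
* `SUITABLE` — everything else.

Environmental status takes precedence where both apply: a protected peak
above the elevation ceiling is environmental. The usable-area denominator
excludes **both** unsuitable categories, so that density × usable area
equals the count on exactly the support where the final surface is
non-zero; this keeps the polygon correction exact. (Whether legislative
land belongs in the denominator is a genuine open choice; excluding it is
the conservation-consistent one.)

The dependent variable is y = log₁₀(d + 1) of the suitability-adjusted
density d (head km⁻²); the inverse transform clips negatives to zero.

## Sampling and bootstraps

Points per polygon: n = max(1, round(A · ρ / 10,000)) with ρ = 30 points
per 10,000 km² by default (an override exists for very large regions, but
it is never automatic). Placement is area-true: a non-legislative cell is
chosen with probability proportional to its area, then the point is
uniform within the cell. The "five files" of the bootstrap design are five
*independent re-placements* of the whole point set; each file is split
5 times into 75/25 train/test (round-half-up on the train size, at least
one test point). All randomness flows from one seed through numpy
`SeedSequence` spawning, so every stage is reproducible in isolation.

## Paired-quadratic forward stepwise regression

Per stratum (and once unstratified), OLS on y grows from the intercept;
candidate covariates enter as (x, x²) pairs, with covariates standardised
within the fitting set before squaring (tames quadratic collinearity;
predictions are invariant — coefficients are reported in standardised and
raw form). At each step the pair minimising AIC is the candidate, with

AIC = n ln(RSS/n) + 2(k+1),  2Δℓℓ = n ln(RSS_prev / RSS_new),

and it is accepted only if all three hold:

1. (AIC_prev − AIC_cand)/|AIC_prev| ≥ 0.01 (skipped if AIC_prev = 0, where
   the relative rule is undefined);
2. 2Δℓℓ ≥ 6 (≈ χ²₂ at p = 0.05 — `halting_pvalue` recomputes this);
3. entered terms after acceptance ≤ ⌊n/15⌋, counting linear and quadratic
   terms separately against the *point* count n (counting unique polygons
   instead is a plausible alternative reading; the point count is used).

The fit halts at the first rejection, and also when RSS ≤ 1e−12·TSS — an
effectively exact fit, where ratios of floating-point residual noise must
not drive further steps. Rank-deficient candidates are skipped with a
warning. A stratum is refused outright with fewer than 30 *unique*
observations (points from the same polygon share one dependent value). If
the unstratified pool itself is refused the run aborts: no pixel could be
predicted.

## Mosaic, evaluation, ensemble

Per bootstrap and scheme, each pixel gets its stratum model's prediction;
refused strata fall back to the unstratified model (flagged). The
composite takes, per pixel, the scheme whose covering *real* model has the
highest R² or lowest RSE (ties to the configured scheme order); pixels no
scheme covers keep the fallback with provenance code 0. Variants
(unstratified, each scheme, both composites) are scored on the held-out
points by Pearson r and RMSE *on the log scale* — the magnitudes of
typical reported RMSEs (a few tenths) are only plausible there. Undefined
r (zero variance) is flagged, not an error. The final variant is the
better composite only when its pooled RMSE beats the best single scheme by
more than a 1 % relative margin; otherwise parsimony keeps the single
scheme. Pooled (concatenated test points) metrics drive the choice;
per-bootstrap metrics are also reported.

The chosen variant's 25 surfaces are averaged per pixel (mean and
population SD of log densities); density = max(0, 10^mean − 1), zeroed on
both unsuitable categories (a config switch can leave legislative areas at
model values); a CV surface uses the back-transformed per-bootstrap
densities, undefined where the mean density is below 1e−6.

## Corrections

Order is fixed: polygon → national → pig mask. Polygon correction scales
densities within each observed polygon by count/modelled-total; a polygon
modelled at zero but reporting animals has its count spread uniformly over
its suitable pixels (over all pixels with a warning if none). National
correction is a single multiplicative factor per country; it deliberately
perturbs the polygon-level matches, replicating the sequential design.
The pig mask zeroes a country only when all three cultural-exclusion
conditions hold, and is idempotent; it runs last so its zeros survive
(masked countries have no national pig total to violate). Aggregation to
coarser grids (5/10/20 km) operates on head *counts*, never densities, so
totals are conserved exactly; all-nodata blocks stay nodata.

## Synthetic scenarios

The generator emulates the inputs at desk scale, on a 10°×10° tile
(200×200 cells of 0.05°) by default:

* **Covariates** (8): separable moving-average-filtered white noise
  (radius 50 cells — broad climatic surfaces whose correlation length
  rivals the tile and exceeds district size) plus a latitudinal gradient,
  min-max bounded to [−1.5, 1.5] so the quadratic truth spans a realistic
  density range instead of exploding in field tails.
* **Strata**: scheme A = quartile bins of a latent field that is partly
  covariate-driven (ecological zonations are functions of climate) plus
  its own smooth component; scheme B = 3×3 rectangular blocks.
* **Mask**: environmental = top 15 % of an elevation-like field;
  legislative = top 3 % of a separate field, never overlapping
  environmental.
* **Truth**: y = shared base quadratic response in 2–3 covariates, with
  moderate per-stratum deviations of intercept and coefficients (zone
  effects, not separate regimes), plus Gaussian noise of SD 0.1 on the log
  scale, clipped at 0 and zeroed on unsuitable land.
* **Admin hierarchy**: recursive 2×2 splits — 1, 4, 16, 64 units at
  levels 0–3, all in one country; counts integrate truth × pixel area at
  the finest level and are summed up the tree, so nesting is exact by
  construction.

What the generator does **not** emulate: remote-sensing artefacts,
covariate collinearity structure of real MODIS/climate stacks, irregular
polygon geometry, census undercount, or multi-country tiles. Passing tests
show the machinery is correct and that recovery works when the generating
model is in the fitted family; they do not certify accuracy on real data.

Because the synthetic tile holds at most 64 polygons — versus thousands in
a production continental tile — `scenario_run_config()` lowers the
30-unique-observation floor to 1 (the degradation experiment deliberately
trains on as few as one polygon); every other threshold keeps its
production default.

## Recovery and degradation metrics

Parameter recovery is measured as pixel-level Pearson r between
log₁₀(density+1) of the **final masked surface** and the true log-density
map, over all cells: the masked surface is the system's product, and the
truth is defined on the same support (zero on unsuitable land). With
level-2 training (16 polygons) this reaches r ≈ 0.92–0.94 across seeds;
restricted to suitable cells only it is r ≈ 0.8–0.9, the gap reflecting
slope attenuation — within-polygon covariate variation carries no
dependent-variable variation, an intrinsic feature of areal training data.

The degradation experiment trains the full pipeline on counts aggregated
to levels 0/1/2 and scores the ensemble mean against the *observed*
finest-level log-density surface on suitable cells (the observed surface,
not the noiseless truth, is what a practitioner could score against).
RMSE rises monotonically as training coarsens.

## Numerical notes and limitations

* Rasterization is cell-centre containment; boundary ties go to the
  polygon earliest in file order. No resampling: grids must match exactly.
* Sub-cell polygons inherit the area of their one containing cell; the
  sampling floor guarantees them one point regardless.
* The nodata sentinel is per raster (default −32768); −9999 is reserved
  for missing polygon counts only.
* Cell size defaults to 0.00833° (~1 km at the equator) but is a free
  parameter; the synthetic tile uses 0.05° to keep runs desk-sized.
* Backward elimination, interaction terms, regularisation and
  machine-learning regressors are out of scope, as are projected
  coordinate systems and topology repair.
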