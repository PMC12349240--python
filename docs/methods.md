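# Methods

This note records the models implemented in `hydrotherm`, the defaults they
run under, and the choices made where the methodology left room.

## Hydrothermal indexes

Kira's warmth index accumulates growing-season warmth above the 5 °C
threshold,

    WI = Σ_{t_m > 5} (t_m − 5)        [°C·month]

over the twelve monthly mean temperatures t_m; the coldness index
accumulates the deficit below the same threshold,

    CI = −Σ_{t_m < 5} (5 − t_m)       [°C·month, ≤ 0].

Months at exactly 5 °C contribute to neither, which yields the algebraic
identity WI + CI = 12·(t̄ − 5) used as a property test. Xu's humidity index
is the ratio of annual precipitation to accumulated warmth,

    HI = P / WI                        [mm/(°C·month)].

Where WI ≤ 0 the ratio is undefined; the package records NaN and excludes
such cells/stations downstream rather than raising. Published tabulations
of HI print its unit both ways round; the values are only consistent with
mm per °C·month, which is what the package uses.

## Ordinary kriging

Station indexes are interpolated to cell centers by ordinary kriging — the
best linear unbiased predictor with weights constrained to sum to one.
Distances are Euclidean in decimal degrees: the target extents are regional
and mid-latitude, and a degree metric keeps the kriging system consistent
with the grid geometry. The semivariogram is fit to a 12-bin empirical
variogram by least squares weighted by pair counts; the family is
configurable (spherical, exponential, gaussian) with exponential as the
default for climate-station data. Noise-free analytic index fields are
infinitely smooth, so recovery tests against the synthetic ground truth use
the gaussian model, which reproduces such fields to well under 1% of their
range at station densities of one per few cells. Constant fields short-cut
the variogram fit (the empirical variogram is identically zero) and return
the constant exactly. With a zero nugget the predictor interpolates the
stations exactly; leave-one-out cross-validation reports RMSE.

## Geographic gradients

Each index is regressed on longitude, latitude and altitude by ordinary
least squares with intercept (statsmodels), with classical t-test p-values.
The gradient summary rescales the altitude coefficient to a per-100 m delta
so that, e.g., a coefficient of −0.025 °C·month per metre reads as a loss of
2.5 °C·month per 100 m of elevation gain.

## Species thermal profiles

Occurrences are thinned to one record per grid cell (first record in input
order — reproducible without a seed), and index values are read from the
containing cell of each surviving point. Cell membership uses the floor
convention: a point exactly on an interior edge belongs to the north/east
cell. Per-species statistics use the n−1 sample standard deviation, and
species with fewer than five records are excluded (reported, not raised).

The optimal warmth range treats a species' WI records as draws from a
symmetric normal niche and takes the peak width at half height of that
curve:

    PWH = 2.354·S,   optimal range = X ± 0.5·PWH,

covering ≈78% of occurrences. Report tables round half-away-from-zero to
one decimal; all internal computation keeps full precision.

Species are then grouped by mean WI and mean HI into five
moisture–temperature types: WI bins [20,60), [60,75), [75,∞) crossed with
HI bins (<3.5), [3.5,7.5], (>7.5), of which five combinations carry names
(cold-temperate humid; mesothermal xeric; mesothermal humid; warm-temperate
hyperxeric; warm-temperate xeric). The top WI bin is open-ended: the
descriptive upper bound of 90 in the type names would strand species with
mean WI above it. Ties at HI 7.5 stay in the xeric/mesic bin. Combinations
without a named type (e.g. cold and arid) and species with mean WI below 20
return an unclassified flag with the raw bin pair. Classification always
uses computed (unrounded) means; one species in the bundled 44-species
Caragana table has a printed mean WI of exactly 75.0 and therefore
classifies into the warm bin although its published label is mesothermal —
the package does not special-case it, and the published grid's totals
(44 species; 7 cold-temperate; 10 hyperxeric; 8 humid) are unaffected.
Aridity zones follow the HI cuts arid < 3.5 ≤ semi-arid < 5.5 ≤ semi-humid
< 7.5 ≤ humid, lower-inclusive.

## Ensemble distribution modelling

Environmental variables are screened at the sample locations in two passes:
first, while any pair has |Pearson r| ≥ 0.7, the member of the worst pair
with the larger mean absolute correlation against the rest is dropped;
second, the variable with the largest variance inflation factor is dropped
until all VIF < 5. Categorical layers bypass both passes and are one-hot
encoded inside the learners. Every drop is logged with its statistic.

Pseudo-absences are uniform random cells outside presence cells, drawn
without replacement, two independent sets of 8000 by default (capped with a
warning when fewer cells are eligible). Each learner × pseudo-absence set ×
run combination is trained on a stratified 80/20 split (stratification
avoids single-class validation folds on small data) and scored on its
held-out 20% by AUC (midrank Mann–Whitney, ties half-credited) and the True
Skill Statistic, TSS = max over score thresholds of sensitivity +
specificity − 1 with the rule "positive if score ≥ threshold"; the smallest
maximizing threshold is reported. Members with TSS > 0.55 enter the
consensus with weights proportional to their raw TSS; the consensus score
is their convex combination, so it is bounded by the member extremes
cell-wise. Consensus skill is reported on the pooled held-out predictions
of the retained members. The learner registry ships logistic regression
(glm), random forest (rf), gradient boosting (gbm), an L1-regularized
logistic model on quadratic + hinge features (maxent_like) and an optional
xgboost adapter, all at library defaults; the registry is pluggable because
the contribution here is the procedure around the learners, not any one of
them.

All randomness flows from one root seed through named substreams
(per pseudo-absence set, per split, per learner fit), so a rerun with the
same configuration is bit-identical; the manifest records every seed, drop
and evaluation.

## Habitat dynamics

Suitability grids in [0,1] are cut at 0.2/0.4/0.6 into non/minimally/
moderately/highly suitable classes, lower-inclusive (a printed range like
"0.2–0.4" is ambiguous at its endpoints, so one convention is fixed and
logged). Cells above 0.2 (strict) form the potential distribution. Cell
areas use the exact spherical-zone formula R²·Δλ·(sin φ_top − sin φ_bottom)
with R = 6371.0088 km (IUGG mean), which agrees with the cosine-midpoint
approximation to within 0.01% below 70° latitude; class areas are reported
in 10⁴ km² and conserve the unmasked study area. Change maps are the
four-way truth table never/loss/gain/stable of the two presence masks.
Centroids are area-weighted means of presence-cell centers (planar lon/lat
averaging; antimeridian-spanning extents are rejected; a
suitability-weighted variant is available behind a flag). Migration vectors
report the haversine great-circle distance and initial bearing, with
cardinal labels by 45° sectors.

## Synthetic world

The generator emulates the statistical structure of a mid-latitude arid
study region rather than any real dataset: monthly station temperatures are
a 12-month continental baseline cooled by 0.8 °C per degree of northward
latitude and 0.6 °C per 100 m of elevation on a planar DEM, with i.i.d.
Normal noise per station-month (no spatial autocorrelation in the noise, so
kriging recovery stays interpretable); annual precipitation rises 20 mm per
degree eastward from a 150 mm base, floored at zero after noise. Virtual
species draw occurrence cells with probability proportional to a Gaussian
kernel in (WI, HI) space around known optima — the simplest unimodal niche
consistent with the symmetric-normal assumption behind the PWHH range — and
each point is jittered uniformly inside its cell. Defaults (300 stations, a
20°×10° bbox, 2.5′ cells) mirror the structure of a real station network at
the package's working resolution; analysis drivers use 10′ cells and 200
stations so every stage runs in seconds.

What the synthetic world does not emulate: spatially correlated weather
noise, topographically complex terrain, multi-year variability, sampling
bias in occurrence records, and real collinearity structure among many
bioclimatic variables. Passing recovery tests therefore demonstrates the
estimators are correct under the stated model, not that real *Caragana*
data would be free of bias from those sources.

Unbiasedness of the planted-niche recovery additionally requires the WI
values over cells to be (locally) uniformly distributed, which holds in the
flat-DEM, pure-latitude-gradient configuration the recovery tests use; on
worlds with clipped or confounded gradients the sample mean can be biased
at the edge of the support, which is a property of the sampling design, not
of the estimator.

## Numerical choices and degenerate inputs

- HI at WI ≤ 0 → NaN, propagated as nodata.
- Variogram fits bound nugget ≥ 0 and sill ≥ nugget; a singular kriging
  system (coincident stations) raises with the offending neighborhood size.
- Bearing of a zero-length migration vector is 0° by convention; a bearing
  that rounds to 360° is folded to 0°.
- Rasters are exchanged as ESRI ASCII grids with nodata −9999, values
  written with 17 significant digits so write→read round-trips are
  bit-identical; coordinates are WGS84 decimal degrees throughout, grids
  are cell-center registered and stored row-major from the north-west.
- Report rounding is half-away-from-zero to one decimal.

## Problem sizes

The test suite and analysis drivers run everything at desk scale: 40×40 to
120×60 grids, 120–300 stations, 150–500 occurrences, 400–2000
pseudo-absences per set, and the full 3 learners × 2 sets × 10 runs fit
grid (60 models). These sizes were chosen so each stage's statistical
checks (recovery within standard error, oracle equivalence, determinism)
are already sharp while the complete pipeline runs in well under a minute.
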