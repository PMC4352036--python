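# Methods

This note records the scientific and numerical choices behind `sdmtransfer`:
what each stage computes, why its defaults are what they are, and what the
synthetic experiments can and cannot say about real tracking data.

## The analysis in one paragraph

Geolocator fixes from a non-breeding seabird population (October–February,
two fixes per bird-day, per-axis location error on the order of 186 km) are
turned into a use–availability design: fixes inside each month's 50%
kernel-density contour are *presences*, and a fixed 100-km lattice across
the pooled-season 90% contour — replicated for every month with
month-matched dynamic covariates — is the *background*. Per month, 20% of
presences and 100 background points are withheld for external validation.
A boosted regression tree (BRT) relates presence/background to nine
environmental covariates plus month; predictors contributing less than 5%
relative influence are pruned. Fitted models are projected onto covariate
grids and validated internally (cross-validated AUC and percent deviance
explained) and externally, by binning withheld predictions into
equal-interval suitability classes and rank-correlating bin order with the
within-bin presence proportion (binned Spearman r_s), plus a point biserial
correlation (COR) and a calibration curve. The headline experiment crosses
every model with every withheld dataset and a reserved third population to
contrast interpolation (validation inside the training region) with
extrapolation (transfer to a novel region).

## Geometry

All metric operations happen in a Lambert azimuthal equal-area frame on a
sphere of radius 6371.0088 km, centred per population on the fixes'
spherical centroid. Equal-area projection is required because two design
quantities are metric: the 200-km kernel search radius and the
one-point-per-100-km background lattice. Geolocator error (~186 km) dwarfs
ellipsoidal corrections, so a sphere suffices. The frame rejects points
beyond 90° of arc from its centre; ranges spanning the antimeridian work
without special-casing because the projection is computed spherically.

The background lattice anchors at the availability polygon's bounding-box
lower-left corner, offset by half a spacing, so each point represents the
centre of one spacing × spacing cell — "one point per 10⁴ km²" at the
100-km default. Polygon boundaries count as inside throughout (closed
polygons), which makes containment deterministic.

## Density contours

The kernel is the quartic (biweight) kernel truncated at the search radius
— the convention of the GIS lineage this design comes from; "search radius"
vocabulary implies a truncated kernel, not a Gaussian bandwidth. Each fix
integrates to one, so the surface integral equals the fix count (verified
to 1%). The default cell size is 25 km (≤ radius/4, enough to resolve the
kernel while keeping grids small); it is configurable.

Contours are **point-containment** contours: the threshold is the highest
density value t such that fixes lying in cells with density ≥ t make up at
least the stated percentage of fixes; ties break toward the larger
threshold (smaller area). This makes "presences are the fixes inside the
50% contour" an exact counting statement rather than a volume-integral
approximation. Polygons follow the cell boundaries of the density grid.

The seasonal 90% availability contour is meant to be contiguous. The
density support is split into connected components; when the component
holding the most fixes can satisfy the containment level by itself, the
contour is built from that component alone (its threshold re-derived from
the fixes it holds, still measured against *all* fixes), which discards
dense outlying specks. Only if no single component suffices are components
added in decreasing point-count order until the level is reached.

## Sample tables and withholding

Covariates are extracted at the nearest 0.5° cell; dynamic layers are
month-matched (a November row samples the November climatology). Rows with
any missing covariate are dropped and counted — no imputation. The 20%
presence withholding rounds to the nearest integer with halves away from
zero, which reproduces the case study's printed monthly withheld counts
exactly; exactly 100 background points are withheld per month. Combined
(multi-population) tables are balanced by row-count re-weighting by
default, with a `fixed:w` strategy available to apply an externally chosen
down-weight (the case study used 0.76).

## Boosted regression trees

The ensemble is stagewise gradient boosting of small regression trees on
Bernoulli deviance with a logit link (scikit-learn's
`GradientBoostingClassifier` underneath). Tree complexity tc maps to
`max_leaf_nodes = tc + 1`, i.e. a tc-split tree; bag fraction is the
`subsample` rate; sample weights are honoured in both fitting and metrics.
Categorical predictors (month, seafloor class) enter as one-hot columns and
their influences are summed back to the parent predictor.

The number of trees is never set directly: a stagewise scan over multiples
of `tree_step` selects the count minimizing k-fold cross-validated
predictive deviance (smallest count on ties; a selection at `max_trees`
raises a warning). The reported cv AUC and percent deviance explained
(dev = 1 − CV deviance / null deviance, null = each training fold's
weighted base rate) come from the held-out folds at the selected count, so
they are honest out-of-fold quantities; the final model is refit on all
rows at that count.

Tuning follows the conventional rule: for each tree complexity, learning
rates are tried from largest to smallest and the largest one whose selected
tree count exceeds 1000 is accepted; among accepted candidates the highest
cv AUC wins (dev breaks ties). Pruning refits iteratively, removing the
single weakest predictor while it contributes less than 5% relative
influence (split-improvement-weighted, normalized to 100%).

`min_node_size` (default 40, the analogue of gbm's `n.minobsinnode`) is
deliberately generous: static fine-grained layers (distance from seamount,
slope) repeat identically across the five monthly background replicates,
and small leaves let trees memorize individual grid cells through them;
a larger minimum removes that channel while leaving the smooth responses
intact.

Partial dependence ("fitted functions") is computed by brute force on the
logit scale: the focal predictor is clamped to each grid value and the
weighted mean prediction over the training rows recorded; rug positions are
the training deciles. The month-interaction check reports month's relative
influence and, for each numeric covariate, the standard deviation of the
two-way partial-dependence grid after removing additive row/column effects
(zero for a purely additive model).

The default pipeline configuration (tc 2, learning rate 0.06, 3 CV folds,
up to 500 trees in steps of 50) is sized so a full three-model experiment
fits in about two minutes; the tuning rule and 10-fold CV are available
through the configuration for deeper runs.

## Validation

Binned validation uses 10 equal-interval bins over [0, 1], right-closed at
the top (a prediction of exactly 1.0 lands in the top bin). The per-bin
statistic is the within-bin presence fraction,
presences / (presences + backgrounds); r_s is the Spearman rank correlation
(mid-rank ties, two-sided p from the t approximation) between bin rank and
that fraction, over informative bins only. A bin is informative when it
holds at least 5 locations (`MIN_BIN_COUNT`): a proportion estimated from
one or two points carries no rank information, and a single stray point in
a sparse top bin can otherwise flip a clean monotone profile into a middling
correlation. Empty and sparse bins are excluded rather than scored zero,
which avoids manufacturing artificial ties. When fewer than three
informative bins remain — typical when a transferred model predicts
near-constant suitability in a novel region — the pairing is recorded as a
*degenerate* failed validation (r_s undefined) rather than given a number.

A claim of *significant* positive skill additionally requires at least
five informative bins. Under the exact permutation null of Spearman's rho
with k ranked points the smallest attainable two-sided p is 2/k!, so with
three or four bins even a perfect ranking cannot reach the 0.05 level
(2/4! ≈ 0.083); the t-approximation's near-zero p-values in that regime
are artefacts and are not treated as evidence. For the same reason, r_s
values computed over fewer than five informative bins are reported but not
compared against well-supported statistics.

COR is the Pearson correlation between prediction and 0/1 label, invariant
to positive affine rescaling of predictions. Calibration curves report
per-bin (mean prediction, observed presence fraction, count); a calibrated
model lies on the identity.

The validation suite tags each (model, dataset) pair as interpolation when
every population in the test set was among the model's training
populations, and extrapolation otherwise.

## The synthetic world

`synthetic.make_scenario` builds three Southern Ocean regions in the
25–65°S band that share a single latent suitability truth but expose
**shifted covariate availability windows** — the transferability lever. The
truth is logit-additive: a Gaussian temperature preference (optimum 10 °C,
width 3 °C, standing in for a 7–13 °C preferred band — a literal flat
plateau would leave the recovery target, the partial-dependence peak,
undefined inside the band), a soft 50–100 m mixed-layer-depth window, a
current-speed preference peaking at 0.2 m/s, an aversion to eddy kinetic
energy above ~300 (cm/s)², and a mild preference for shallower abyssal
depths. Amplitudes are large (2–6.5 logit units) because use–availability
contrast is inherently weak: usage proportional to suitability against a
background drawn from the same range only discriminates strongly when the
best habitat is orders of magnitude more used than the worst.

Each region parks *different* covariates inside the informative zones of
the shared responses: region A ("pacific", 18 birds, spanning the
antimeridian) exposes the temperature, MLD-rising-edge and depth
contrasts; region B ("indian", 9 birds) the MLD-falling-edge, current and
eddy contrasts; region C ("atlantic", 4 birds, the reserved transfer
target) sits in flat zones of every response, so its realized distribution
is availability-driven. Because trees extrapolate as constants outside
their training range, a model transferred across these windows predicts
near-constant (and typically low) suitability — the designed mechanism for
extrapolation failure, and the reason the disjointness matters: wherever
two regions share an informative zone of a shared truth, transfer
*succeeds*, contradicting the phenomenon under study.

Covariate fields are Gaussian-filtered noise plus deterministic structure
(poleward-cooling temperature, a mid-region bathymetric ridge, an eddy
jet), rescaled into each region's windows; dynamic layers are AR(0.8)
month to month. Field smoothness is chosen per layer: climatology-like
layers (temperature, MLD) are smooth at scales well above the geolocator
error so the error does not destroy their signal; chlorophyll is patchy;
the seamount field is dense (350 seamounts) so distance-to-seamount varies
at short scales. Slope derives from the depth gradient and geomorphology
classes from depth/ridge/seamount geometry, making both depth-correlated
confounds rather than pure noise.

Tracks are sampled points, not a movement model — at two fixes per day and
~186 km error a step-length model is unidentifiable. Each bird-day draws
locations over grid cells with probability proportional to truth times an
isotropic availability kernel (exponential decay, 5000 km range) around a
per-bird monthly centroid that drifts poleward 0.5°/month with a ~6°
monthly relocation walk. The wide kernel and monthly relocation are
deliberate: persistent tight clusters let *every* smooth field — including
pure-noise layers — alias the spatial presence pattern and inflate
spurious influence past the 5% pruning bar. Months are truncated to 28
days so February keeps the two-fix daily cadence. Per-axis Gaussian
location error (default SD 186 km) is applied after sampling.

## What the synthetic experiments do and do not show

They show that the pipeline's machinery is sound: mass-conserving density
surfaces, exact withholding arithmetic, honest cross-validated metrics
(chance AUC and ~zero deviance explained on permuted labels), recovery of
a known response optimum, pruning that keeps truth covariates and drops
independent noise in a majority of simulated worlds, and the
interpolation/extrapolation contrast under a known covariate-shift
mechanism. They do not show that real grey petrel models would attain any
particular AUC or r_s: real fields are cross-correlated in ways the
generator only sketches, real availability is shaped by wind and
life-history rather than an exponential kernel, and real transfer failure
mixes covariate shift with genuine preference differences that a shared
truth cannot represent.

## Numerical details and limitations

- Determinism: every stage is seeded; refitting with the same seed
  reproduces metrics exactly, and rasters are bit-identical on rerun.
- Probabilities are clipped to (1e-12, 1 − 1e-12); deviances use the same
  guard.
- Contour polygons follow density-grid cell boundaries; a degenerate
  surface (all mass in one cell) yields that cell's box.
- The per-run problem sizes (three 70°×26° regions at 0.5°, ~4800/2500/1100
  fixes, ~7000-row design tables, ≤500 trees with 3-fold CV) were chosen so
  a complete experiment runs in minutes on one core; all are configurable
  upward.
- Known limitations: influence shares of correlated spatial fields are
  noisy, so pruning outcomes near the 5% bar vary between seeds; the
  equal-interval binning is scale-sensitive, which is why degenerate
  (near-constant) prediction sets are reported as failed validations rather
  than numbers; and month can acquire a small genuine influence through the
  seasonal drift interacting with monthly covariates even when the truth
  has no month effect.
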