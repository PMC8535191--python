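# Methods

## The model

`cliffsdm` fits a presence-background maximum-entropy niche model: the
probability that a presence falls in background cell *x* is the Gibbs
distribution

    p(x) = exp(βᵀ f(x)) / Σ_j exp(βᵀ f(x_j)),

where the sum runs over the background sample and *f* expands the raw
predictors into feature classes — Linear (the min–max scaled variable z),
Quadratic (z²), Product (zᵢ·zⱼ for variable pairs) and Hinge (forward ramps
max(0, z−t)/(1−t) and reverse ramps max(0, t−z)/t with knots *t* at evenly
spaced background quantiles, 50 per orientation by default).  All features
are rescaled to [0, 1] by background min/max, and the same stored expansion
is applied to any cell — training, present or future — so projections are
expansion-consistent by construction.

Fitting maximizes the mean presence log-likelihood minus per-feature L1
penalties

    (1/m) Σ_i βᵀf(x_i) − log Σ_j exp(βᵀf(x_j)) − Σ_k λ_k |β_k|,
    λ_k = RM · β_class(m) · max(sd_k(presences), floor) / √m,

with the published Maxent default interpolation tables for β_class (L:
(10,30,100)→(1.0,0.2,0.05); Q: (0,10,17,30,100)→(1.3,0.8,0.5,0.25,0.05); P:
(0,…,100)→(2.6,…,0.05); H: 0.5), pinned in `config.BETA_TABLES`.  The
presence-sample standard deviation in the penalty is floored (default 0.05 on
the [0, 1] feature scale) so a feature constant across presences still
carries a finite penalty and coefficients cannot diverge on separable data.

The optimizer is proximal gradient (ISTA) with backtracking line search: the
penalized objective is monotone non-increasing by construction (asserted in
tests), the step grows 1.25× after each accepted step, and convergence is
declared when the relative objective change falls below `convergence_tol`
(default 1e-7) or after `max_iterations` (default 1000).  Any convex solver
meeting the same tolerance would be interchangeable; the contract is the
objective, not the algorithm.

Suitability is reported on the cloglog scale of Maxent v3.4,
`1 − exp(−e^H · raw(x))`, where H is the entropy of the raw distribution over
the training background; raw output is retained for AICc.  Exponents are
capped at 700 so projection cells far outside the training envelope saturate
instead of overflowing.

## Tuning, evaluation, thresholding

Candidates are the 13 feature-class combinations (L, Q, H, LP, LQ, LH, PQ,
PH, QH, LPQ, LPH, LQH, PQH) crossed with regularization multipliers 1.0–5.0
in steps of 0.2 (21 values, 273 candidates).  Each candidate is fit on all
presences; AICc = 2K − 2ll + 2K(K+1)/(n−K−1) uses the raw scores
re-standardized over *all* study-area cells, ll summed at the occurrences,
K = the number of nonzero coefficients, and is flagged invalid when
n − K − 1 ≤ 0.  The smallest valid AICc wins; ties break by smaller K, then
smaller RM, then combo order, making selection permutation-invariant.

Discrimination metrics come from a seeded random k-fold (default 10)
cross-validation of the selected settings: presences are partitioned, the
background never is; AUC is the rank (Mann–Whitney, ties ½) probability that
a held-out presence outscores a background cell; TSS = sensitivity +
specificity − 1 at the fold's training threshold.  The 10-percentile training
presence threshold is pinned as the ⌈0.1·m⌉-th smallest training presence
cloglog score (so at most 10% of training presences fall below it); the
binarization boundary is inclusive (suitable at exactly τ).  AUC/TSS could
equally be reported from the tuning run's own folds or from a fresh
cross-validation of the winner; this package reports a single seeded 10-fold
run of the selected settings.

Permutation importance permutes one variable jointly across presences and
background, averages the training-AUC drop over `n_perm` permutations, and
normalizes to 100.  Percent contribution is explicitly a surrogate: Maxent's
own contribution bookkeeping is path-dependent (it accrues objective gains
along the particular training trajectory) and cannot be reproduced outside
it, so the share Σ|β_k|·sd_bg(f_k) per variable is reported instead, and only
the importance *ranking* should be compared across implementations.

## Occurrence handling

Cleaning applies three discard rules in a fixed order, recording the first
match: (i) outside the known-range polygon, (ii) not expert-verified,
(iii) coordinate uncertainty strictly above 1 km (the analysis cell size).
Records with missing coordinates are a hard error, not a discard.

Thinning is the spThin algorithm: while any record has neighbours closer
than the thinning distance (1.5 km default), remove one uniformly random
record among those with the most such neighbours; repeat over 100 replicates
(the replicate count plays the role spThin calls iterations) and keep the
first replicate with the largest retained count.  The retained *count*, not
the identity of records, is the tested contract.  An exhaustive
maximum-independent-set oracle (≤ 20 records) measures the heuristic's
optimality rate: ≥ 95% over random small instances.

## Cliff delineation

The baseline is a coastline polyline; transects are cast every 5 m of arc
length (count = ⌊L/spacing⌋ + 1), perpendicular to the moving-average
smoothed vertex tangents, pointing to the configured land side (default:
land left of the direction of travel).  Profiles are bilinear DTM samples
every `step` m.  The Top/Toe scan is this package's concrete instantiation of
a cliff-delineation rule whose published form delegates detail to a GIS
tool: walking inland, the Toe is the first sample above 1 m elevation, the
candidate run is the maximal contiguous ascending run with per-step slope
≥ 30%, the Top is the run's last sample, and the pair qualifies iff the
overall Top–Toe slope is ≥ 70% *and* the Top is at ≥ 15 m altitude.  The 1 m
toe and 30% per-step parameters are exposed in config; the manual inspection
and editing step of a GIS workflow is replaced by include/exclude transect-id
lists.  On the synthetic world this scan has recall and precision 1 against
the configured cliff segments at zero terrain noise.

The distance-to-cliffs predictor is the per-cell minimum Euclidean distance
from cell center to any Top point (planar; haversine for lon/lat), computed
with the same scalar expression as a brute-force double loop so the two agree
exactly.  Cell membership anywhere in the package uses cell centers and
half-open cell extents [x, x+cs) × (y−cs, y].

## Range change and land use

The dispersal-limitation polygon is the exact convex hull of the thinned
presences, buffered outward 2 km, with the cell mask additionally cropped to
shore distance ≤ 7 km.  Change accounting masks *both* the present and future
binary maps when constrained (cells outside the polygon count as absent in
either period), then counts maintained (1→1), lost (1→0) and gained (0→1)
cells; the identities maintained+lost = current and maintained+gained =
future are asserted on every call, and net gain = 100·(future−current)/current
to one decimal.  High-suitability counts use a strict > 0.60 comparison
(the inclusive/exclusive choice is unknowable from the protocol text; pinned
strict and configurable).  Land-use overlap reports the percentage of
predicted presence cells per class over the five classes {Water, Forest,
Scrubland, Cropland, Urban}; an empty prediction yields an all-zero row
flagged extinct, and presence cells without a land-use class go to an
`unclassified` audit column excluded from percentages.

## The synthetic world

The generator emulates the *statistical structure* the analysis assumes, not
any real geography.  Defaults: a 116 × 85 lattice of 1 km cells (9860 cells,
a realistic cell count for a ~100 km coastal study region), a 10 m DTM on a 2 km
coastal strip, a sinusoidal north–south coastline, and two cliffed segments
with 30 m tops over 20 m faces (slope 150%).  Terrain is analytic: elevation
0 at the waterline, a 2% background rise inland, and linear cliff faces —
so profile extraction can be checked against a closed form.

Climate fields are a linear spatial gradient plus a stationary Gaussian
random field (Gaussian-filtered white noise, correlation length 5 km),
standardized to the prescribed mean and SD exactly: bio9 21.69 ± 0.72 °C,
bio12 60.01 ± 6.88, bio15 64.73 ± 2.55.  (The configured bio12 units are
treated as opaque — the generator reproduces moments only.)  Gradients are
oriented mostly alongshore (80°/90°/20°): a cross-shore climate gradient
would be confounded with the distance-to-cliffs predictor, and the whole
point of the synthetic design is that every effect in the truth is
identifiable.  Realized pairwise |r| stays below the 0.75 screening cut.

Presences are sampled multinomially with cell weight ∝ exp(η*), where the
generating truth is a Linear+Quadratic form over min–max scaled predictors:
a dominant coastal decay (−7 on distance to cliffs) plus mid-range optima
(+12/−12 on bio9, +10/−10 on bio12, +2/−2 on bio15).  The curvature is
deliberately strong: with gentle humps the quadratic structure is not
identifiable against hinge approximations and "LQ-generated" would be an
empty claim.  Records are jittered within their cell, given uncertainties
≤ 1 km, and the `dirty` option corrupts disjoint subsets (displaced out of
range / unverified / uncertainty > 1 km) with exact bookkeeping so cleaning
counts can be asserted.

Future scenarios shift each climate field linearly so its mean and SD land
on the published per-GCM/period/RCP values (5 GCM labels × 2050/2070 ×
RCP 4.5/8.5 = 20 projections); the distance-to-cliffs grid passes through
untouched, as the same object.  Future land-use grids come from a trivial
per-cell redraw sampler, declared *not* to be a land-use change simulation
model.  Every artifact is bit-reproducible from its seed.

What the synthetic world does **not** emulate: real spatial autocorrelation
structure of climate anomalies (future deltas are spatially uniform shifts),
observation bias (off by default), coordinate error beyond uniform in-cell
jitter, terrain noise, and any real coastline geometry.  Passing tests
therefore demonstrate the machinery is correct and self-consistent, not that
any particular real-world result would be reproduced.

## Desk-scale sizes

Unit and end-to-end runs relax two things through configuration while
leaving the defaults at protocol values: transect spacing (100 m instead of
5 m against the 10 m DTM) and a reduced tuning lattice (the recovery
experiment: all 13 combos × RM {1, 3, 5}; the demo pipeline: three combos ×
RM {1, 2, 3}; both with 8 hinge knots per orientation) — choices made for
desk-scale runtime and stated wherever used.  The model-recovery harness uses m = 500 presences and
N = 5000 background cells; the tuner-recovery experiment runs 50 seeded
replicates and counts a replicate as recovered when the selected combo nests
L+Q or the best LQ-family candidate is within ΔAICc ≤ 2 of the winner.

## Known limitations

- Only the ESRI ASCII grid raster format is supported (plain text,
  bit-exact round trips); no GeoTIFF, no reprojection engine.
- Percent contribution is a magnitude surrogate (above); compare rankings,
  not values.
- The spThin heuristic is not exact; its optimality is measured, not proven.
- AICc's K uses nonzero-coefficient counts, which depend on the optimizer's
  hard zeros produced by soft-thresholding; a different solver could count
  near-zero coefficients differently.
- The dispersal polygon's cell mask uses cell centers; boundary cells can
  flip with tiny geometry changes.
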