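# Methods

## Grid-square system

All spatial aggregation uses the Japanese standardized grid-square system:
the Basic (1 km) Grid Square spans 30″ of latitude by 45″ of longitude,
with an 8-digit code built from the first-mesh indices (⌊lat·1.5⌋,
⌊lon⌋−100), the 10 km subdivision digits (0–7), and the 1 km digits (0–9).
Each halving level (500 m, 250 m) appends one quadrant digit numbered
SW=1, SE=2, NW=3, NE=4; the 100 m level appends a latitude digit then a
longitude digit (0–9 each) to the 1 km code. 250 m and 100 m codes are
both 10 digits, so a code string is always carried together with its
level.

Cell membership is half-open, `[south, north) × [west, east)`, which makes
the tiling a partition: a point on a shared edge belongs to exactly one
cell. Internally every cell is a pair of integer row/column indices
counted from latitude 0 / longitude 100°; neighbourhood and coresidence
tests are integer Chebyshev arithmetic on those indices, so they cross
parent-cell boundaries correctly. A tolerance of 1e−9 cell widths
(≈ 0.1 µm) is absorbed when flooring a coordinate, so coordinates computed
*from* a cell edge re-encode to that cell.

Residential-grid merging treats two candidate grids as coresident when
every pair is at Chebyshev distance ≤ 2 (distance 1: adjacent; distance 2:
a shared adjacent cell exists). That is queen contiguity — the permissive
reading of "adjacent or sharing the same adjacent grid". A stricter rook
mode (Manhattan distance ≤ 2) is available via `adjacency="rook"`.

## Trajectory reconstruction

Duplicate-minute logs are averaged in degree space (unweighted arithmetic
mean of latitude and longitude). Gaps between consecutive observed points
of a user are filled with one point per missing minute, equally spaced on
the straight segment in longitude/latitude degree space. Interpolation is
planar, not geodesic: at the ~100 m working resolution and the within-city
gap lengths involved, the planar/geodesic discrepancy is orders of
magnitude below the grid-cell size. Interpolation runs across calendar-day
boundaries first; interpolated points dated on a day that is not valid for
the user (fewer than 24 logs) are then deleted. Observed points are never
deleted by this step. A `max_gap_minutes` guard exists but is off by
default — unbounded gaps are intentional, because overnight interpolation
is precisely what motivates the residence-stripping step.

Thresholds: a valid day needs ≥ 24 accuracy-filtered raw logs (counted
before minute deduplication); an active user needs ≥ 11 valid days ("more
than 10" read strictly). The accuracy filter keeps logs strictly below
200 m. Timestamps are naive local time; the target setting (Japan) has no
DST.

## Residence estimation

The 5% log set takes `k = max(1, ⌈0.05·n⌉)` points from each end of a
day's time-sorted points, or the whole day when the ends would overlap
(`2k ≥ n`); the ceiling-with-floor-of-one rule guarantees non-empty sets
on sparse days. Within-day modal-grid ties break to the lexicographically
smallest code — any deterministic rule works; this one needs no extra
state. Each day contributes exactly one modal grid to the across-days
tally. The 5% sets are drawn from the trajectory points (observed plus
interpolated); drawing from raw observed points only is a switch
(`estimate_residence` accepts any point table).

The residence point is the mean of all 5%-set points inside the
residential grid(s). Stripping removes every trajectory point (observed or
interpolated) whose 250 m cell is residential, for that user only.

## Exposure

Land-use input is a table of 100 m cell codes with one of 17 original
categories, reclassified to 8 working types; public facilities and parks
and green spaces merge into parks/public, all non-urban categories and any
cell absent from the table become `other`. Buffer containment is a
haversine distance test from the trajectory point to cell centroids
(radius 100 m inclusive, Earth radius fixed at 6,371,000 m) —
mathematically identical to testing centroid-in-circular-buffer, exact,
and fast. The indexed query inspects only the point's cell-index
neighbourhood (the window size is derived from the radius and the minimum
cell extent in the mesh domain, 92.6 m, so no qualifying centroid can be
missed); tests and the acceptance script verify exact agreement with a
full O(N) scan. Counts are visit frequencies: a cell hit by m points of a
user-day counts m times. Both observed and interpolated points contribute.

## Step model

The model is

    y_ud = β_0u + β1·SEX + β2·AGE + Σ_k s_k(ln(LANDUSE_udk + 1)) + ε_ud,
    ε_ud ~ N(0, σ²_L1),  β_0u ~ N(α, σ²_L2)

with SEX ∈ {0 male, 1 female}, AGE ∈ {10,…,60} by decade (70+ removed in
preprocessing). Each s_k is a cubic B-spline with a second-order
difference penalty (P-spline), basis dimension 10 by default, constrained
to sum to zero over the training data so that α is identifiable; the
penalty null space that survives the constraint (the linear trend) is
unpenalized. The random intercept is the standard variance-component
construction: ridge-penalized user indicator columns whose smoothing
parameter equals σ²_L1/σ²_L2. All smoothing parameters are chosen jointly
by minimizing the profiled Gaussian REML criterion over log-smoothing
parameters (L-BFGS-B with numerical gradients, bounds e⁻¹⁸…e²⁵); σ²_L1 is
the profiled scale. REML is used because the model contains variance
components, for which marginal-likelihood criteria are the robust
standard.

Per-smooth p-values are approximate Wald-type tests: the coefficient block
against its Bayesian posterior covariance, at degrees of freedom equal to
the rounded block EDF (pseudo-inverse truncated to that rank). They are
reported as approximate; significance is flagged at p < 0.05. A smooth
whose exposure index is constant in the training data is dropped (it
contributes 0 and is reported as such). Constant parametric columns raise
a rank-deficiency error naming the columns.

Fixed-effects prediction is `α̂ + Σ ŝ_k(x_k)`, deliberately omitting sex,
age, and user intercepts, because the prediction targets are users whose
demographics are unknown. Exposure indices outside the training range use
the spline's natural extrapolation and are counted in a logged warning.

The implementation was validated against an independent reference
(`mgcv::gam` with P-splines and a random-effect smooth, REML), run via
Rscript in the test suite: variance components agree within a fraction of
a percent and fitted smooth curves are numerically indistinguishable on a
common synthetic dataset. The reference is a cross-check only; no fitted
quantity comes from it.

## Mapping

Day types: Saturdays, Sundays, and a configurable holiday list (defaults
for October 2019: the 14th and 22nd) are weekend/holiday; the four weekend
pairs (Oct 5–6, 12–13, 19–20, 26–27) are additionally summarized
separately. User means are unweighted over the user's available dates per
cell; a user's per-weekend mean uses whichever of the two days has a
prediction (the both-days-only restriction is off by default). Users map
to the 500 m parent cell of their residence point; grid rows with fewer
than five users are suppressed. The user-count-weighted grand mean over
grids equals the mean over included users exactly.

## Synthetic world

The generator is a pure function of (config, seed) and emulates the data's
structure, not behaviourally realistic mobility:

- **Landscape** — a concentric city on 100 m cells: high-rise core
  (< 1.2 km from centre), dense low-rise ring (< 3.5 km), low-rise
  periphery (< 8 km), a 1 km road lattice, radial railway lines, seeded
  park and factory patches, remainder `other` (about half of the `other`
  cells are omitted from the emitted table to exercise the
  absent-cell-defaults-to-other rule).
- **Users** — 200 by default; homes at the centre of 250 m cells drawn
  from a pool of 20 residential cells 1.5–7 km from the centre (clustered
  so the ≥ 5-user mapping rule is satisfiable); a deterministic 20%
  minority reports daily steps with complete sex/age; others are mostly
  attribute-missing.
- **Days** — anchor paths home → 1–3 destinations → home over a
  07:30–21:30 window, destinations downtown (55%), mid/outer ring (20%)
  or near home; minute positions by linear interpolation between anchors.
  Logs are sampled at geometric gaps targeting 60 emitted logs/day
  (oversampled by a fixed factor 1.12 because home-cell masking removes
  the home-dwell logs, about an eighth of samples), with 30 m Gaussian
  position noise, 5% duplicate minutes, lognormal accuracy values with a
  10% tail at 200–400 m, and deletion of every log in the home 100 m
  cell.
- **Steps** — drawn from the model equation with α = 7700, β_sex = −400,
  β_age = −20, σ_L1 = 2000, σ_L2 = 500 and documented piecewise-linear
  true smooths (rising for high-rise/parks/railways, falling beyond a
  threshold for low-rise/factories, flat for roads/other — qualitative
  shapes only, not estimates). True exposure is computed on the minute
  path with home-250 m-cell points excluded, mirroring the pipeline's
  residential stripping. Counts are floored at zero; the flooring rate is
  below 1% under the defaults.
- **Storm scenario** — on one configured weekend (default Oct 12–13)
  destination distances shrink by a factor 0.15 and downtown trips are
  disabled, producing a detectable step deficit in the mapped output.

What passing tests show — and what they do not: the pipeline recovers
planted residences, generator smooths, and variance components under
*this* generative model; real data add transport modes, indoor/underground
dropout, spatially correlated GPS error, and attribute biases that the
generator deliberately omits, so the tests validate the machinery, not
real-world accuracy.

For model-recovery studies a direct exposure-record generator
(`generate_model_records`) skips the GPS layer and samples zero-inflated
log-uniform counts so every smooth's range is covered; the study size used
in the recovery tests is 200 users × 20 days.

## Numerical and degenerate-input choices

- Half-open flooring tolerance 1e−9 cells; buffer boundary inclusive
  (measure-zero either way, inclusive is deterministic).
- Interpolation emits nothing for 1-minute gaps; non-increasing timestamps
  or mixed users are errors.
- Empty user-days produce no exposure record; an exposure record of all
  zeros predicts `α̂ + Σ ŝ_k(0)`.
- REML failures of positive-definiteness return +∞ to the optimizer; the
  final solve re-runs at the optimum.
- Deviance explained is 1 − RSS/null-RSS with fitted values including the
  (shrunk) user intercepts, matching the usual additive-model convention.

## Problem sizes

Default test and acceptance sizes: 200 users × 31 days (≈ 3.3 × 10⁵ raw
logs, ≈ 9 × 10⁶ trajectory points after interpolation) for the end-to-end
study, and 200 × 20 records for model recovery. The full study runs in
about a minute on one CPU; processing is vectorized throughout
(integer-key membership tests, chunked buffer counting on a dense type
raster).
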