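# Methods

This note documents the models, conventions and numerical choices behind
`homerange`, in the spirit of the methods documentation of the larger
statistical-ecology packages: enough detail that a user can tell exactly
what quantity each function returns and where the defaults come from.

## Data model

A `Track` is one *sampling instance*: a time-ordered sequence of planar
coordinates (meters, projected CRS identified by an EPSG code),
timezone-aware timestamps (stored UTC), and optionally a per-fix HDOP
(horizontal dilution of precision, a unitless GPS quality scalar). Tracks
are sorted on construction; duplicate timestamps keep the first fix and
warn; geographic (longitude/latitude) CRSs are flagged and rejected by all
estimators — area in m² is only meaningful on a projected plane. The
Movebank CSV dialect is projected on read; the built-in projections are the
conterminous-US Albers equal-area conic (EPSG:5070) and WGS84 UTM zones,
implemented from the standard (Snyder) series with sub-millimeter forward
error.

Regularization (`resample_track`) anchors windows at the first fix floored
to the interval and keeps, per window, the first fix within `tolerance` of
the window start. It never interpolates: every output fix is an input fix,
and the operation is idempotent. Weekly grouping floors timestamps to
week boundaries; weeks start Monday 00:00 by default (`week_start`
configurable; some ecosystems default to Sunday), and the paper-style
weekly workflow keeps only weeks with strictly more than 10 fixes
(`min_n = 11`).

## Geometric estimators

**MCP.** Centroid = unweighted mean of x and y. Distances to the centroid
are peeled at the level-α quantile computed with linear interpolation (the
R type-7 convention); this convention is load-bearing — nearest-rank
variants retain a different point set at small n and change the printed
area. The hull is exact (floating-point convex hull + polygon area).

**k-LoCoH.** Each local hull uses n points *total* (focal point plus n−1
neighbors); whether the focal point counts toward n differs across
software, so an off-by-one against other implementations is possible and
documented here. Hulls are sorted by area with ties broken by fix index
(deterministic output); coverage counting is boundary-inclusive
point-in-polygon. `n="auto"` uses ⌈√N⌉. Degenerate hulls (collinear or
duplicated neighbors) are skipped with a warning. Only k-LoCoH is
implemented (no a-/r-/T-LoCoH).

## Movement models and likelihood

Three stationary Gaussian processes per axis, axes independent and sharing
parameters (isotropy; anisotropic variants are out of scope):

| model | parameters (beyond the 2-D mean) | position autocovariance at lag t |
|---|---|---|
| iid | σ² | σ²·1[t = 0] |
| ou  | σ², τ_pos | σ² e^(−t/τ_pos) |
| ouf | σ², τ_pos, τ_vel | σ² (τ_pos e^(−t/τ_pos) − τ_vel e^(−t/τ_vel))/(τ_pos − τ_vel) |

Units: σ² in m² per axis, timescales in seconds; τ_vel < τ_pos strictly
(the OUF form is degenerate at equality). GPS error adds independent
per-fix, per-axis variance (uere·HDOP)²/2, so uere is the 2-D RMS error in
meters per unit HDOP; fixes without HDOP use HDOP = 1. `uere` is supplied
(calibrated externally, e.g. 1.67 m for the collars in the bundled
examples); estimating it from the data is not exposed.

The log-likelihood is the exact Gaussian density of the observed positions,
evaluated in O(n) by a Kalman recursion — a 1-D state per axis for OU and
the exact discretization of the (position, velocity) state space for OUF
(transition e^(A·Δt) in closed form from the eigenstructure; innovation
covariance Q = P∞ − Φ P∞ Φᵀ; stationary initialization). The recursion is
verified against dense multivariate-normal densities built from the ACF to
1e-8 on all three models, for regular and irregular sampling, with and
without the error model. The stationary mean is set to the sample mean and
held fixed (not profiled by generalized least squares) — an approximation
that is immaterial at the sample sizes involved but counted in the AICc
parameter totals (iid 3, ou 4, ouf 5).

**Fitting.** Positive parameters are optimized on the log scale
(Nelder–Mead, function tolerance 1e-8); τ_vel is parametrized as
τ_pos·sigmoid(g) to enforce the ordering. Starting values come from the
empirical variogram (sill → σ²; lag at 63.2% of the sill → τ_pos;
τ_vel = τ_pos/10), with two additional starts at ×0.1 and ×10 on the
timescale. `"auto"` fits all three models and returns the lowest AICc,
with AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).

**Effective sample size.** `dof_area = n / (1 + 2 Σ_{k=1}^{n−1}
(1 − k/n) ρ(k·Δ̄t))` with ρ the fitted normalized position ACF, Δ̄t the
median sampling interval, and the sum truncated once ρ < 1e-3. It equals n
exactly for an uncorrelated fit and decreases monotonically in τ_pos. This
is the classical autocorrelation-inflation formula for the variance of a
mean; reference aKDE implementations derive an area-specific degrees of
freedom that can differ by roughly a factor of two on strongly
autocorrelated data, so absolute aKDE areas should be compared across
packages with that in mind (see Limitations).

## Utilization distributions

UDs live on a `TemplateRaster`: square cells, extent = bounding box of the
fixes expanded by a buffer (default "auto" = half the larger bounding-box
span) with `ncol = 200` columns by default. The grid stores per-cell
**probability masses** (summing to 1), not densities; divide by cell area
for densities.

**KDE** uses per-axis bandwidth h_i = sd_i·n^(−1/6) (per-axis sample sd
with ddof = 1; some packages pool the axes, shifting areas at the percent
level). Kernels are evaluated exactly at all cell centers via a separable
matrix product (no truncation radius), then normalized.

**aKDE** replaces n by `dof_area`: h_i² = sd_i²·dof_area^(−1/3). Using the
per-axis sample sd (rather than the fitted isotropic σ²) makes the
reduction exact: an uncorrelated fit reproduces the KDE bit for bit. With
an error model, each fix's kernel is widened by its own error variance:
h_i,k² = h_i² + (uere·HDOP_k)²/2. Area confidence intervals treat the
implied variance as χ²: bound = estimate·ν/χ²_{ν,q} with ν = 2·dof_area
and q ∈ {0.975, 0.025} for (lci, uci). This is a deliberate simplification
of the reference ecosystem's area CIs; the CI polygons are the estimate
polygon scaled about its centroid so feature area equals the bound (a
presentation device, not a spatial inference).

**Cumulative UD and isopleths.** `hr_cud` ranks cells by density and
assigns each the cumulative mass of all cells at least as dense; tied
densities share the larger cumulative value, so the CUD is well defined on
plateaus (a perfectly uniform UD has CUD ≡ 1 and admits no sub-unity
isopleth). The level-α member set is the smallest set of highest-density
cells holding ≥ α of the mass (the crossing cell included —
`ud_level_mask`). Isopleth polygons are marching-squares contours of the
cumulative surface (grid padded so boundary contours close), assembled into
polygons with holes by containment parity. Contouring the cumulative
surface rather than the density surface makes polygon membership match the
mass interpretation directly; polygon areas agree with cell counting to a
few percent at the default grid and converge as `ncol` grows.

## Overlap indices

For fitted estimates A, B at level α (m = cell masses):

- `hr` = area(A_α ∩ B_α)/area(A_α) — directional, in [0,1];
- `phr` = Σ of A's UD mass in cells whose centers fall in B_α — directional;
- `vi` = Σ min(m_A, m_B); `ba` = Σ √(m_A·m_B); `hd` = 2(1 − ba);
- `udoi` = area(A_α ∩ B_α) · Σ(m_A·m_B)/cell_area (≥ 0; 1 for identical
  uniform UDs, > 1 for strongly concordant non-uniform pairs).

When the two UDs live on different grids, the pair is evaluated on the
finer grid (deterministic tie-break), the other UD re-rasterized by
cell-center sampling and renormalized — this makes vi/ba/udoi/hd exactly
invariant under argument swap. `conditional=True` truncates each UD to its
level-α member set and renormalizes first. Values are clamped to their
ranges ([0,1] or ≥ 0) against last-ulp float excursions. Note hd = 2 (its
maximum) for disjoint UDs.

## Synthetic data

`simulate_track` draws *exact* stationary samples: OU by its AR(1)
discretization (φ = e^(−Δt/τ), stationary start), OUF through the same
closed-form state-space discretization the likelihood uses — so simulator
and likelihood agree by construction and parameter-recovery tests are
clean, with no time-stepping bias. Error injection draws HDOP from a
constant or log-normal law, then adds Gaussian noise of variance
(uere·HDOP)²/2 per axis; positions are drawn before error, so uere = 0
reproduces the error-free track bit for bit at the same seed. All
randomness flows through one seeded generator per call.

The fixture suite emulates a small mustelid-style GPS study: six animals
(three per sex), hourly fixes over 10 weeks, per-animal OU parameters drawn
from log-normal laws around σ² ≈ 0.5 km² and τ ≈ 4 h (males ×2 in σ², a
common mammalian pattern), log-normal HDOP (median 2), uere = 1.67 m — the
calibration value used in the worked examples. The toy landscape is
thresholded smoothed noise hitting a target forest fraction. What the
synthetic data do **not** emulate: habitat-biased or state-switching
movement, fix failures and irregular duty cycles, heavy-tailed error;
passing tests demonstrate correctness of the estimators under their own
model assumptions, not robustness to such features of real data.

## Problem sizes and determinism

The default test suite and the acceptance script run on simulated tracks of
n ≤ 2,000 (50,000 for moment checks of the simulator alone), 100–200-column
grids, and 20 replicates for model-selection rates — sizes chosen so the
whole suite completes in a few minutes on one core while leaving the
statistical tolerances meaningful. Estimation is fully deterministic given
the input; only simulation consumes seeds, every stochastic routine takes
one explicitly, and repeated runs produce byte-identical CSV/GeoJSON
outputs.

## Known limitations

- Isotropic covariance only; no anisotropy, drift, or periodic (circulation)
  models, and no occurrence-distribution (kriging/bridge) estimators.
- `dof_area` and the aKDE area CI are documented approximations, not the
  reference ecosystem's exact formulas; absolute aKDE areas carry an
  oversmoothing bias of order dof_area^(−1/3) (≈ +20% at dof ≈ 100), which
  cancels in relative comparisons across animals or weeks.
- The normal-reference bandwidth is the only KDE bandwidth (no
  cross-validation or plug-in rules); no boundary correction.
- Projection support covers EPSG:5070 and UTM; other projected systems must
  be projected upstream.
- Raster output is plain single-band TIFF with a JSON geometry sidecar, or
  text ESRI ASCII grid — not a georeferenced GeoTIFF.
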