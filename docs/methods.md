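# Methods

This note documents the statistical procedures, the choices made where a
convention had to be fixed, what the synthetic generator does and does
not emulate, and the known limitations.

## Raster model

A `Grid` is a 2-D double-precision field with an axis-aligned affine
georeference (origin at the outer NW corner, row 0 = north), an EPSG
code, and a validity mask (numpy.ma convention: True = invalid). GeoTIFF
is the canonical format; files carry ModelPixelScale, ModelTiepoint, a
minimal GeoKey directory, and the GDAL nodata tag, so round-trips are
value- and mask-exact and the files open in standard GIS software. CRS
support is deliberately narrowed to EPSG codes: the pipeline only ever
aligns resolutions on a shared coordinate system, never reprojects.

Alignment resamples a grid onto a reference geometry. Continuous fields
use bilinear interpolation; categorical fields must use nearest
neighbour. Bilinear is conservative: if any of the four contributing
cells is masked or outside the source extent the output cell is masked —
no NDVI is fabricated at lake or nodata edges. A zero-weight neighbour
(query exactly on a cell-center row/column) is exempt, so single-row and
edge geometries interpolate correctly. All pipeline statistics run on
the NDVI stack's geometry; drivers are aligned to it.

## Compositing

Sub-monthly composites are reduced per month by the per-cell maximum
over unmasked inputs (masked only where all inputs are masked). The
growing season is May–September. Two annual reductions exist because the
field's phrase "average of the maximum NDVI values" is genuinely
ambiguous: `monthly_max_mean` (default) averages the five monthly
maxima, `seasonal_max` takes the single seasonal maximum. One mode is
declared per run and recorded in the manifest; change-point and trend
results must not mix modes. In `monthly_max_mean` a cell missing any
season month is masked rather than averaged over a shorter season, since
a missing July is not exchangeable with a missing May.

The regional series is the unweighted mean over valid cells. A
latitude-cosine weighting would change regional means by well under the
interannual noise at the ~4° extents this pipeline targets, so equal
weights are the default and only documented path.

## Ordered cluster analysis

For a gap-free annual series the scan evaluates
S_n(τ) = V_τ + V_{n−τ} for 2 ≤ τ ≤ n−2 — both segments keep at least two
points so the jump test is always defined at the optimum. The scan is
O(n) via prefix sums; tests verify it against a direct brute-force
evaluation. Ties at the minimum resolve to the earliest τ and are
recorded in the result; a constant series is flagged "no change point".
Interior local minima of S_n within 10% of the global minimum are
reported as secondary valleys (diagnostic only; multiple valleys suggest
more than two regimes).

The jump statistic is the standard pooled two-sample t,
|T| = |x̄_τ − x̄_{n−τ}| / (s_p √(1/τ + 1/(n−τ))). The default critical
value is the standard-normal quantile at 1−α — the convention that
prints 1.64 at α = 0.05, which this line of applied work quotes — with
the strict two-sided quantile (1.96 at α = 0.05) behind `two_sided=True`.
Degenerate zero-variance cases: |T| = ∞ (unequal means, significant) or
0 (equal means). A noise-free mean shift, adding a constant, or scaling
the series leave |T| respectively infinite, unchanged, and unchanged.

Identifiability: simulations during design showed that locating a pure
step to ±1 year at n = 39 with ≥95% reliability needs a shift of about
3 within-segment standard deviations; at exactly 2σ the rate is ~82%
regardless of estimator. The recovery study in the tests and acceptance
script therefore uses a 3σ step. Note also that a continuous
piecewise-linear kink with no level jump does *not* put the S_n valley
at the kink — OCA detects jumps in the segment means, and the generator
is built accordingly (below).

## Trend and coverage classification

θ_slope is the exact OLS slope on the time index i = 1…n, computed
per cell from the normal equations over that cell's valid years (≥3
required, else masked and counted). Trend bins: the published table's
interior bins overlap at their endpoints, so the convention here is
extreme bins closed (≤ −0.0019, ≥ 0.0006) and interior boundaries
belonging to the bin on their right-open side: mild degradation
(−0.0019, −0.0010), basically stable [−0.0010, −0.0002), slight
improvement [−0.0002, 0.0006). Coverage bins are left-open right-closed
at 0, 0.2, 0.4, 0.6, 0.8, 1, with everything at or below 0 classed bare.
Both tables partition their domains; boundary membership is tested
explicitly.

Class-share rates are OLS slopes of each class's percentage share on the
calendar year, in percentage points per year. Per-pixel trend
significance is deliberately not computed: the class tables are defined
on raw slopes.

## Correlation

Per-cell Pearson r between annual NDVI and each driver, over the jointly
valid years of that cell; cells with fewer than 5 valid pairs (the
post-split segment here has 11 years) or zero variance are masked and
counted. Two-sided p-values (t on n−2 df) are stored for reference but
never used to mask: the maps show raw r. In area summaries, cells with
r exactly at the threshold (default 0) count to the positive share.

## Geodetector

q = 1 − SSW/SST with population variances in both numerator and
denominator — the one convention in which the stratum-size weights
cancel exactly; mixing sample and population variances is the classic
implementation bug and is foreclosed by computing sums of squares
directly. q is clipped to [0, 1] only against rounding; the tests check
agreement with direct summation to 1e−12.

Discretization uses Jenks natural breaks: a dynamic program over the
sorted values finds the contiguous k-partition minimizing total
within-class SS (verified against exhaustive search). Thresholds are
reported as the smallest member of each upper class; stratification puts
a value equal to a threshold into the upper stratum. Default k = 5 per
continuous factor, configurable; aspect and land use are declared
categorical and pass through (natural breaks on circular degrees or
class codes would be meaningless).

Sampling draws n distinct random cells (seeded) and drops any point with
a masked value in the response or any factor layer — the operational
definition of "outliers removed" here; the count is reported. The
default n is 1678 points, matching the scale such studies use.

Significance defaults to a seeded permutation test (p with the +1
correction, so the minimum attainable p is 1/(1+n_perm)); calibration
under a true null is part of the acceptance checks. The noncentral-F
reference of the original Geodetector software is available as
`method="noncentral_f"` for comparability.

The interaction detector overlays two factors' strata (occupied pairs
only) and classifies q(A∩B) against q(A), q(B): independence within
ε = 1e−6, then nonlinear enhancement (> sum), double-factor enhancement
(> max), nonlinear weakening (< min), single-factor nonlinear weakening
(otherwise). On a common sample the overlay refines both partitions, so
q(A∩B) ≥ max(q(A), q(B)) holds structurally — enhancement is the generic
outcome; the weakening categories can only arise across differing
samples or discretizations, but are classified per the standard taxonomy
regardless.

## Synthetic scenes

`make_scene` generates: a base NDVI field rising along the NW→SE
diagonal (default 0.50→0.75, re-centred to a 0.625 regional mean); a
regional year effect with two mean-anchored trend segments — slope
−0.0004 NDVI/yr before the split (after 2009 by default) and
+0.0018 NDVI/yr after, the second segment's mean sitting 0.04 NDVI above
the first's — plus seeded interannual noise (sd 0.005) and independent
per-cell-year noise (sd 0.02). These defaults keep regional means inside
the 0.62–0.67 window typical of the emulated region and give the mean
jump that OCA needs: design simulations showed the noise-free S_n valley
of a jump-free kink lands years late, whereas with the level jump the
valley sits exactly at the designed split and the ±1-year recovery rate
under default noise exceeds 95%.

Each growing-season month gets a zero-mean seasonal offset (July peak)
and two sub-monthly composites equal to the monthly value minus
nonnegative "atmospheric" deficits, of which the smaller is always zero —
so MVC recovers the monthly field exactly, which the tests assert.

Drivers live on a coarser grid (default 25×25 against the 50×50 NDVI)
and pass through the alignment path in every end-to-end run.
Precipitation shares the NDVI diagonal gradient most tightly (making it
the top-q factor by construction); soil temperature, soil moisture and
elevation carry the gradient with increasing noise; temperature and
evapotranspiration follow a W→E gradient; aspect, land use, GDP and
population density are uncorrelated with NDVI. Annual driver anomalies
are coupled to the NDVI year effect with positive coefficients, so
NDVI–driver correlations are positive on average.

`make_stratified_response` builds a response whose stratification
explains exactly a target share of variance in expectation: equally
spaced stratum means standardized (occupancy-weighted) to between-strata
variance = target_q, plus within-stratum Gaussian noise of variance
1 − target_q. Deterministic means keep the realized q tightly
concentrated; the acceptance checks recover targets 0.2 / 0.5 / 0.76
within ±0.05 at n = 1600.

What the generator does not emulate: sensor artifacts and quality flags,
spatially correlated noise (a smoothing option is deliberately absent
rather than half-supported), non-Gaussian interannual variability,
physically coupled climate–vegetation dynamics, and realistic land-use
geometry. Passing tests therefore demonstrate the correctness of the
statistics and the plumbing, not the ecological fidelity of any
conclusion drawn from real data.

## Problem sizes

Default end-to-end runs use a 50×50 scene over 39 years (390 sub-monthly
grids), 1678 sample points, and 299 permutations per factor; the
acceptance script's simulation studies use 500–1000 replicates per
check. These sizes make every property measurable with comfortable
statistical margins while keeping a full run in seconds.

## Known limitations

* No reprojection between coordinate systems; inputs must share a CRS.
* NetCDF support is read-only and limited to the NetCDF3 classic format.
* Single change point only; multiple regimes are surfaced as secondary
  S_n valleys, not segmented automatically.
* No spatial-autocorrelation correction in correlation or detector
  p-values; both treat cells/points as exchangeable units.
* The Geodetector "risk" and "ecological" detectors are out of scope.
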