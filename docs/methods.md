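# Methods

This note records the statistical models implemented, the defaults and why,
the numerical choices made where conventions diverge, and what the synthetic
validation does and does not establish.

## Coordinates and geometry

All computation is planar, in kilometers. Longitude/latitude inputs are
projected once at read time with a spherical azimuthal equidistant projection
centered on the data centroid (Earth radius 6371.0088 km). Distances from the
center are exact great-circle distances; at provincial extents (a few hundred
km) the distortion elsewhere is far below the precision of any statistic
here. Polygon areas come from shapely on the projected vertices. Points on a
shared boundary of two regions are assigned to the first containing region in
input order — an arbitrary but deterministic rule, stated so results are
reproducible.

## Nearest-neighbor index

The estimator is the plain within-window mean of each point's distance to its
nearest other point, with the Clark–Evans expectation r̄_exp = 1/(2√D) at
density D = n/A and standard error 0.26136/√(n²/A) for the z-test. Two
deliberate choices:

* **No edge correction.** Boundary points lack neighbors beyond the window,
  which biases r̄_obs (and hence R) slightly upward. The uncorrected
  estimator is the GIS-standard one, and the synthetic CSR calibration below
  quantifies the effect instead of correcting it: at n ≈ 500 on a 1400 km²
  window, the mean R over 200 replicates stays inside [0.97, 1.03].
* **Classification couples R with significance.** clustered if R < 1 and
  p < 0.05 (two-sided normal), uniform if R > 1 and p < 0.05, random
  otherwise. R alone is not enough at small n.

Duplicate coordinates are legal (real POI data contain them), contribute
zero distances, and trigger a warning rather than an error. The statistic
needs n ≥ 2, and the area must be supplied from region polygons, a convex
hull, or an explicit value — the choice materially changes r̄_exp and is
therefore always explicit in the API.

## Kernel density

The kernel is the bivariate quartic K_h(d) = 3/(πh²)(1 − (d/h)²)² for d < h.
With each point carrying unit mass the surface integrates to n, so values
read as facilities/km² (count-scaled, not a probability density). Densities
are evaluated at cell centers; no partial-cell masking is applied at region
edges. Mass conservation holds within 1% once the cell size is ≤ h/10 and
kernel supports fit inside the extent — the test suite checks exactly that.
The default bandwidth is the standard-distance rule
h = 0.9·min(SD, √(1/ln 2)·D_m)·n^(−1/5) with SD the RMS distance and D_m the
median distance to the mean center; an explicit bandwidth always overrides
it. If the median distance degenerates to zero (half the points at the
center), SD alone is used rather than failing.

## CRP supply–demand matching

CRP_i reduces to the ratio of the facility share to the elderly-population
share; region areas cancel algebraically and are carried only as metadata.
Two conventions are fixed:

* the matched band is inclusive on both boundaries (lo ≤ CRP ≤ hi), with
  strict inequalities for advanced/lagging;
* values are classified unrounded; a 3-decimal display value (round half
  away from zero) is reported alongside.

The population-share-weighted mean of all CRPs is identically 1 — a free
integrity check applied to every table. The sensitivity analysis reclassifies
each city under alternative bands and reports per-band counts, the list of
cities that change class, and the agreement fraction. Because widening only
the matched band can move cities into (never out of) the matched class,
matched counts must be monotone in band width; the report computes counts by
actual reclassification so this structural constraint always holds, which
also guards against transcription errors in externally supplied count tables.

## Geographical detector

q = 1 − Σ n_h σ_h²/(Nσ²) with population variances throughout: the n_h σ_h²
weighting is exactly the within-stratum sum of squares only under the
population convention, so mixing in sample variances would silently change
q. Singleton strata are legal (σ_h² = 0). q is clamped only against negative
floating-point dust below 1e-12; any larger negativity is a bug and raises.

**Significance.** F = (N−m)/(m−1)·q/(1−q) — identically the one-way ANOVA F
statistic — referred to a noncentral F(m−1, N−m; λ) with
λ = [Σ_h ȳ_h² − (Σ_h √n_h ȳ_h)²/N]/σ², the standard geodetector test. The
first sum is deliberately unweighted; the n_h-weighted variant that sometimes
appears in secondhand descriptions makes the test wildly conservative
(measured rejection rate ~0 at α = 0.05 under the null, versus ≈ 0.04 for
the form used here, which the suite verifies at N = 140, m = 5 over 1000
replicates).

**Discretization.** Natural breaks is exact Jenks via dynamic programming
(O(kn²), verified against exhaustive partition enumeration); quantile uses
sample quantiles; standard deviation places breaks at mean + s(j − k/2) with
the sample (ddof = 1) standard deviation; geometric interval shifts the data
so the minimum maps to 1 and places breaks at powers of r = max′^(1/k) —
a deterministic reconstruction, since the GIS algorithm of that name is
unpublished. Breaks that would leave a class empty are merged with a warning
and the realized k is reported. The per-factor search maximizes q over
method × k (k = 3..10, clipped to the number of distinct values; candidates
must leave ≥ 2 non-empty strata), breaking ties toward smaller k and then a
fixed method order — reproducibility over cleverness. No cross-validation is
attempted: with N in the tens, held-out folds would be too small to rank
schemes stably, so straight maximization is used and the optimism this
induces is measured instead (see the null calibration below).

**Interactions.** The overlay stratum of a pair is the observed label pair.
Typing compares q12 with min, max and q1+q2 under a relative tolerance of
1e-9; "independent" (q12 = q1+q2 exactly) is measure-zero in practice. By
refinement monotonicity the overlay can never have q12 below max(q1, q2)
(splitting strata never increases the within sum of squares), so the two
weakening types are unreachable for exact overlays — the classifier keeps
them for API completeness, and the impossibility itself is a tested
property. An overlay exactly tying max(q1, q2) (e.g. a factor overlaid with
itself) is typed as the non-enhancement boundary case.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design the package targets: a tessellated
study region of ~14 comparable city units, facility point processes, and a
city table of one response plus nine covariates.

* **Tessellation** — axis-aligned square cells (default 2×7 at 10 km);
  analytic areas make geometric oracles exact.
* **Point processes** — homogeneous Poisson (CSR, default intensity
  5/km²), Thomas cluster (parents Poisson, offspring Poisson(mean 20),
  Gaussian displacement σ = 0.2 km by default), and a square lattice with
  optional uniform jitter. Clipping to the polygon (with a 4σ parent pad
  for the Thomas process) rather than toroidal wrapping: edge effects are
  part of what the uncorrected nearest-neighbor estimator sees, so the
  simulation should include them. A resource guard refuses expected counts
  above 10⁷.
* **City table** — n units (default 140 to give the detector statistics
  room; the real-data analogue of 14 units is deliberately *not* the test
  default, because variance-based recovery targets are meaningless at
  n = 14) assigned round-robin to m strata (default 5). Stratum means are
  equally spaced and scaled to population between-variance q_target; the
  within-stratum noise variance is (1 − q_target)·n/(n − m), which cancels
  the (n_h−1)/n_h small-sample bias of population variances so the
  *expected* q of the true stratification equals q_target. The planted
  factor is the stratum mean plus 5% observation noise; the eight decoys
  are independent standard Gaussians. The continuous response is mapped to
  facility-like counts (300 + 80y, rounded, floored at 0); rounding
  perturbs q by O(10⁻⁵) and exact-q=1 constructions (noise_sd = 0) survive
  it because equal means round equally.

Not emulated: road networks, population rasters, spatially autocorrelated
covariates, inter-city migration. Passing the recovery tests therefore shows
the estimators are correct and calibrated under the stated processes — not
that real covariates are as cleanly separable as the planted factor.

Every operation takes one seeded generator per call; identical configs give
byte-identical outputs, which the pipeline manifest (SHA-256 of every
report) makes checkable end to end.

## Validation scales

Deterministic checks run at full precision. Stochastic calibrations use the
sizes at which their targets are sharp enough to be meaningful: 200 CSR
replicates at n ≈ 500 for the mean-R band, 100 replicates each for the
cluster/lattice regime checks and for parameter recovery (mean q within
±0.05 of targets 0.3/0.6/0.9; planted factor ranked first in ≥ 90%), 1000
null replicates for the significance test's type-I error ([0.03, 0.07] at
α = 0.05), 500 random instances for the q/ANOVA identity and 200 for
Jenks-vs-enumeration (n ≤ 12, k ≤ 4, where enumeration is exact and cheap).

## Known limitations

* The Yingkou row of the bundled Liaoning table is internally inconsistent:
  its published CRP (1.099) is not reproducible from the published
  approximate population column (which gives 1.111), so baseline class
  counts computed from raw columns (7/3/4) differ from those computed from
  the published CRPs (6/4/4). Both routes are exposed; `carescape.datasets`
  documents the caveat.
* The nearest-neighbor z-test assumes the CSR null and is used descriptively
  for observational point sets; no edge correction (above).
* The discretization search's maximized q is optimistically biased at small
  N; the null calibration (q_target = 0, n = 140) bounds the optimism rather
  than correcting it.
* Geometric-interval breaks are a reconstruction of an unpublished
  algorithm; schemes chosen by the optimizer rarely depend on it.
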