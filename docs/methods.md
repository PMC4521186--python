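# Methods

This note records the models, conventions and numerical choices behind
`coastspan`, and what the synthetic-world experiments do and do not
demonstrate.

## Geometry and the along-coast axis

All distances are great-circle distances on a sphere of radius 6371.0 km
(haversine form; the radius is a fixed constant so measured ranges are
bit-stable). A coastline is a directed polyline; `s` increases from the
first stored vertex — a file-level convention of the coastline inputs.
Projection of a point onto a coastline searches every polyline segment
using chord-parameterized interpolation of the vertex unit vectors
(normalize(a + t·(b − a)), t clamped to [0, 1]); positions beyond the
terminal vertices clamp to the terminus. Interpolation *onto* the polyline
(`point_at_s`, used by locale discretization and the generator) inverts
that same parameterization with a short fixed-point iteration, so a point
constructed at position `s` reprojects to `s` at machine precision —
discretize-then-measure round trips are exact, which is what makes
end-to-end parameter recovery a sharp test rather than an approximate one.

## Range-quantification rules

Along-coast gaps and spans are measured as differences of `s` (an
along-shore metric, consistent with tracing a coastline with a measuring
tool), not as point-to-point chords. The rules:

- isolated single occurrences: 50 km;
- consecutive occurrences on one coast strictly more than 1500 km apart
  break the range; each group measures as its span;
- every segment length is floored at 50 km, the measurement resolution.
  Without the floor, two nearly coincident points would measure ~0 km and
  a duplicate point could *shrink* a total; with it, totals are ≥ 50 km,
  order-invariant and duplicate-invariant;
- occurrence clusters farther than 1000 km from every continental
  coastline are archipelago distributions, clustered per species by
  single linkage with a 1000 km radius (the only island-scale constant in
  the problem) and measured as the maximum pairwise great-circle distance
  in the cluster — the only orientation-free reading of a "straight line
  through" a cluster;
- totals sum per-coast segments and archipelago spans.

Cleaning drops exact (0, 0) coordinates, invalid coordinates, per-species
duplicate coordinates, and points farther than a configurable offshore
tolerance (default 100 km ≈ the 1° grid scale; no canonical value exists)
from every coastline. Every drop is logged once with a reason code.
Whether literature-derived points should also be subject to the 1500 km
split is genuinely open; the package applies all rules uniformly to all
cleaned points regardless of source.

## Climatology extraction

Grids are 1°×1° fields per variable × three-month block, read/written as
dense CSV (lat, lon, value; missing = land). A point samples the cell
containing it; if that cell is masked, the nearest unmasked cell centre
(ties broken lexicographically by (lat, lon)) within a bounded search
radius (default 5° of arc) substitutes; beyond the radius the point
contributes missing data for that variable and is excluded from its
statistics.

Season labels resolve to month blocks through each point's own hemisphere
(southern seasons shifted six months), so an equator-straddling species
mixes blocks per point. Two block conventions are supported — the default
quarter-aligned blocks (winter = Jan–Mar, spring = Apr–Jun, …) matching
quarter-aligned ocean climatology products, and a meteorological
alternative (winter = Dec–Feb) — switchable in configuration; spring must
contain the northern spawning peak, which both satisfy.

Per-species statistics use the sample SD (n − 1; a single value has SD 0
by convention). Annual statistics pool the four seasonal values of every
occurrence rather than sampling a separate annual-mean field: an
annual-mean field would make the "annual SD" purely spatial, whereas the
pooled version captures the seasonal variability that makes it a
meaningful predictor; the annual range (temperature, salinity) is max −
min of that pool, i.e. across the year and across occurrences.

A structural caveat: statistics computed *across a species' occurrences*
(SDs, ranges, minima/maxima) partially encode the species' spatial extent
itself. A species spanning 10,000 km of a monotone thermal gradient
necessarily has a large temperature SD, so such covariates correlate with
the response by construction. This is a property of the study design being
implemented, not of the synthetic world; interpret their importances
accordingly.

## Model competition

Predictor pruning builds connected components of the |Pearson r| > 0.9
graph, lets each component absorb variables correlated above 0.7 with a
member, and keeps one representative per extended cluster — a forced
variable if present (defaults: spring mean current speed and spring mean
temperature), otherwise the member with the highest mean |r| to its
cluster. Constant columns are excluded with a warning (undefined
correlation).

Response and predictors (including 0/1 trait dummies) are z-scored with
the sample SD, so coefficients are standardized betas; scaling constants
are retained for back-transformation. Fits use statsmodels OLS;
rank-deficient designs raise an error naming the collinear columns.

AICc uses the Gaussian log-likelihood up to a constant: AIC = n ln(RSS/n)
+ 2p with p = k + 2 (intercept, error variance, k slopes), plus the
correction 2p(p + 1)/(n − p − 1). The n ln(2π) + n constant is omitted;
ΔAICc, weights and RVI are invariant to that convention, but absolute
AICc values are comparable only within one convention. Exact fits
(RSS = 0) and samples with n ≤ p + 1 raise errors.

All 2^V subsets plus the null model are fitted (refused above V = 20
unless forced). Subsets are enumerated in a canonical sorted order so
rankings cannot depend on caller ordering; AICc ties break on the variable
tuple. RVI is computed over the 40 lowest-AICc models with weights
renormalized within that subset (ties at the 40th place widen the
subset); the summary table (best four models per size up to seven
variables, plus the null) likewise renormalizes weights across the shown
set, with per-coefficient significance flagged at two-sided p < 0.05.
Residual skewness and kurtosis of the best model are reported as a
normality diagnostic; no automatic transformation is applied. Missing
predictors are handled by complete-case analysis (dropped and logged), not
imputation.

## The synthetic world

The generator's defaults are the study conditions the pipeline is meant to
operate under, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_species | 138 | species per dataset |
| years | 1850–2012, median 1954 | first-introduction years |
| analysis year | 2012 | reference for years-since-introduction |
| slope_time | 37.8 km/yr | generative range-expansion rate |
| intercept | 138 km | generative range at introduction |
| target_r2 | 0.20 | population R² of the time-only model |
| trait effects | habitat −0.19, body size +0.15, salinity −0.20 (standardized) | injected covariate effects |
| floor | 50 km | measurement resolution |
| coasts | 4 × 17,500 km | near-meridional jittered polylines |
| point spacing | ≤ 200 km, endpoints included | occurrence density |

Introduction years are drawn as stratified halves — exactly ⌊n/2⌋ species
uniform on [1850, 1954], the rest uniform on [1954, 2012] — so the sample
median sits at the configured median year to within ~2 years instead of
drifting by up to ±15 under an i.i.d. mixture.

True ranges follow `range_i = clamp(m_i · η_i, 50, total coastline)` with
`m_i = 138 + 37.8 t_i + Σ β_j · SD_y · z_ij`. Trait effects are specified
as standardized betas; SD_y is implied by the time-only R² target, and the
residual noise scale is what remains of `noise_sd_for_r2(slope, Var(t),
R²)` = slope·√(Var(t)(1 − R²)/R²) after the trait contributions (an error
is raised if the requested effects exceed the residual budget).

**Noise family.** The noise factor η_i is a shifted gamma with mean 1,
common variance, and per-species support η_i ≥ 50/m_i. Rationale: real
range-size data are strongly right-skewed (50 km floor, maxima above
20,000 km), and with additive Gaussian noise of the calibrated variance
roughly a quarter of species would fall below the floor, whose clamp then
attenuates recovered slopes far beyond sampling error. The shifted-gamma
support makes the floor structural — no censoring at all, so OLS on the
(exactly measured) ranges is unbiased for the generative slope — while
keeping tails light enough that the finite-sample mean R̂² stays within
about +0.01 of the population target (very heavy-tailed factors, e.g. a
lognormal of the same variance, inflate mean R̂² at n = 138 by ≈ +0.03).
Typical realizations reach maxima around 20,000–35,000 km, the right order
for coastal invaders. An additive `normal` mode is retained for
comparison; its floor censoring is counted in the generator report.

Salinity effects use the generator's own analytic latitudinal salinity
profile evaluated at a species' latitude centre, so the effect is
recoverable by the climatology-extraction stage. Occurrence placement lays
evenly spaced points (≤ 200 km apart, both endpoints included) spanning
exactly the true range, centred on the species' latitude centre, spilling
onto further coasts when a range exceeds one coastline and optionally
splitting ranges across two coasts (sub-ranges ≥ the floor, summing
exactly). A species at the floor is emitted as one isolated point. With
these defaults measurement round-trips are exact to < 1e−6 km, so
parameter-recovery experiments isolate statistical error from geometric
error.

What the generator does **not** emulate: GBIF record-density and
reporting biases, detection lags, taxonomic error, non-meridional or
fractal coastline geometry, and spatially correlated climatology noise.
Passing tests therefore validate the measurement rules, the calibration
algebra and the model-selection machinery — not robustness to real-data
pathologies.

## Recovery experiments and problem sizes

The standard experiment (`coastspan.experiments.slope_recovery_experiment`)
runs 200 replicates of 138 species through generation → placement →
cleaning → assignment → segmenting → totals → time-only OLS, with
per-replicate seeds spawned from one master seed. One replicate estimates
the slope with SE ≈ 7 km/yr, so the mean over 200 replicates carries a
Monte-Carlo SE ≈ 0.5 km/yr; observed means sit within one SE of
37.8 km/yr, and mean R̂² within ~0.01 of 0.20. The whole experiment takes
roughly 90 s on one CPU; test fixtures use smaller worlds (10–80 species)
chosen to exercise every rule, including forced multi-coast splits and
floor species.

## Known limitations

- Coastline projection assumes reasonably smooth polylines; a polyline
  that doubles back within the offshore tolerance could project ambiguous
  points to either branch.
- Archipelago spans use the maximum pairwise distance; for strongly
  curved island arcs an along-arc measure would be longer.
- The competition refits each subset independently (no QR updating);
  V = 11 → 2048 OLS fits ≈ 3 s, fine at this scale but not for V ≫ 15.
- `waterfall` latitudinal bands cover coast-attached points only;
  archipelago clusters carry no band.
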