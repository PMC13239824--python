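# Methods

This note documents the models implemented in `refugia`, the choices made
where the methodology was genuinely open, and what the synthetic test bed
does and does not establish about behaviour on real data.

## Spatial data model

All layers are single-band rasters on a regular geographic (lon/lat) grid
with cell-center registration, row 0 at the northern edge, and an explicit
validity mask. Layers entering one computation must agree exactly in
shape, transform and CRS; misalignment is always an error, never an
implicit resample, so no stage can silently shift data. Nodata propagates
conservatively: a cell invalid in any input is invalid in the output.

Area statements use per-cell geodesic areas on a sphere of radius
R = 6371 km — a cell spanning latitudes [φ₁, φ₂] and Δλ degrees has area
R²·Δλ_rad·(sin φ₂ − sin φ₁) — instead of an equal-area reprojection. The
full-sphere tessellation sums to 4πR² to machine precision, and area
weighting enters every range-area, mean-elevation, centroid and coverage
statistic. Distances and bearings are great-circle (haversine / initial
bearing); the deviational ellipse alone uses a local equirectangular plane
about the point centroid, where the planar error at basin scale (~100 km)
is far below the ellipse's own sampling noise.

Rasters persist as ESRI ASCII grids with 17-significant-digit floats, so a
write/read round trip is bit-exact and every artifact is a plain text file
any GIS can open. Protected areas travel as GeoJSON polygons and are
rasterized by cell-center containment; phylogenies as Newick.

## Occurrence preparation and variable screening

Thinning keeps at most one record per species per 0.1° × 0.1° cell
(grid anchored at (0°, 0°), half-open edges, first record in input order
retained — the order-dependence is documented rather than randomized so
reruns are identical). Species with fewer than five thinned records are
excluded. The fixed order is thin → filter → screen.

Collinearity screening is iterative and fully deterministic: while any
pair of layers has |Pearson r| ≥ 0.8 over the cells jointly valid in all
layers, the member of the worst pair with the larger mean |r| to all
remaining layers is dropped (ties alphabetical); afterwards, while any
variance inflation factor VIF_j = 1/(1 − R²_j) ≥ 10, the worst layer is
dropped. Every elimination is recorded with its reason, and the kept set
is guaranteed to satisfy both thresholds on recomputation. VIFs are
computed by least squares on the common support; perfect collinearity
reports as infinity rather than a large number.

The pipeline screens climate and distance variables but, by default,
withholds static topography (DEM, slope, aspect) from the SDM candidate
set (`PipelineConfig.predictor_exclude`). With a single lapse rate,
elevation and temperature are near-duplicates (r ≈ −0.99), and which of
the pair survives pairwise screening is decided by chance correlations; a
surviving static DEM absorbs the thermal niche and forces future
projections toward "no change". Topography remains in the stack for
stratification and elevation statistics.

## Ensemble SDMs

Per species: presences are the unique grid cells containing records; 1000
pseudo-absence cells are drawn uniformly from valid non-presence cells
without replacement (with-replacement fallback plus warning when the grid
is too small; no exclusion buffer is applied around presences). Evaluation
uses ten stratified 75/25 splits with seeds `base_seed + repetition`; a
member that cannot fit on a split (e.g. too few presences for the
envelope) or a single-class split skips that repetition with a warning.

AUC is the probability that a random presence outscores a random absence,
ties counting ½, computed by the rank-sum identity with midranks. TSS is
maximized over candidate thresholds — the midpoints of adjacent unique
scores plus the two extremes, with presence at score ≥ threshold; ties
among maximizing candidates resolve to the middle tying candidate so the
reported cut always achieves the maximum.

Members clear the ensemble gates with mean AUC > 0.9 **and** mean
TSS > 0.8; the ensemble is the TSS-weighted mean of qualifying members'
suitabilities. If no member qualifies the single best-TSS member is used
and a prominent warning logged. The continuous ensemble is binarized at
the max-TSS threshold of the *pooled* (across repetitions) ensemble
validation scores; the same threshold converts both scenarios.

Three members ship natively:

- **SRE** (surface range envelope): the [q, 1−q] percentile box
  (default q = 0.025, linear-interpolation percentiles) of presence
  values; presence iff all variables inside. Fit from scratch; absences
  ignored.
- **Additive-logistic (GAM-style)**: each covariate enters through a
  linear term plus Gaussian bumps anchored at 16 training quantiles
  (bandwidth 1.5× the center spacing), with a mildly ridge-penalized
  (C = 2), class-balanced logistic fit over the summed bases. Local bases
  let the model express narrow unimodal responses without saturating its
  probabilities — saturation would make the downstream max-TSS threshold
  degenerate. A global-quadratic variant was rejected for exactly that
  reason: under the ridge needed for stability it cannot represent niches
  much narrower than the basin-wide covariate spread.
- **Tree ensemble**: gradient-boosted shallow trees (depth 3, 200 rounds,
  learning rate 0.1, imbalance handled by `scale_pos_weight`), which fit
  sharp niche edges from few presences better than bagged deep trees.

Other algorithms plug in through the two-method contract
(`fit(X, y)` / `predict(X) → [0, 1]`, deterministic under a fixed seed).

## Habitat quality

Degradation of cell x with land-cover class j:

    D_xj = Σ_r (w_r / Σ_r w_r) Σ_{y ∈ Y_r} r_y · i_rxy · β_x · S_jr

where Y_r is the set of cells with positive intensity of threat r
(intensities are not renormalized), w_r the threat weight, β_x an optional
accessibility raster (default 1), S_jr the sensitivity of class j to
threat r, and i_rxy the distance decay from source y: linear
1 − d/d_rmax or exponential exp(−2.99·d/d_rmax), both exactly zero beyond
the maximum effective distance d_rmax (km). Distances are great-circle
between cell centers. Quality discounts the per-class habitat suitability
H_j through a half-saturation response:

    Q_xj = H_j · (1 − D^z / (D^z + k^z))

Defaults k = 0.5 and z = 2.5 are the canonical values of this model
family; both are exposed in configuration and echoed into output
metadata. The implementation accumulates per-source contributions over a
window bounded by d_rmax (latitude-aware) and is verified against a
literal quadruple-loop evaluation to 10⁻¹⁰; Q = H_j/2 at D = k holds to
10⁻¹².

## Diversity, range dynamics, conservation overlay

Faith PD uses the rooted convention (the connecting subtree includes the
path to the root, so a single-species cell scores its root-to-tip
distance; the root's own subtending edge is never counted). The unrooted
convention is available by flag. The implementation is a tip × edge
incidence-matrix reduction — an edge contributes wherever at least one
tip below it is present — verified cell-by-cell against edge-union
enumeration and against the reference R implementation (picante,
`include.root = TRUE`).

CSH = (A_future − A_current)/A_current × 100 on geodesic areas; an empty
current range makes CSH undefined (reported as missing, never as a
number). CSH ≤ −50% is flagged as drastic shrinkage. Elevation shifts are
reported in metres and percent. Range centroids average cell-center unit
vectors in 3D (area-weighted; optionally suitability-weighted) and
re-normalize to the sphere; an exactly antipodal mass distribution is a
documented error. Direction bins are quadrants about north with half-open
edges (NE = [0°, 90°), …), so exact cardinal bearings bin
deterministically.

Top-fraction masks threshold at the (1−q) linear-interpolation quantile of
valid-cell values with all ties included; a constant layer masks
everything and warns. The combined hotspot is the **union** of the three
top-5% masks (SR, PD, HQ) — consistent with high inter-layer overlap in
the motivating analyses — with the strict triple intersection available.
Priority areas default to (union of top-10% SR/PD/HQ) ∩ (top-10% projected
species loss); the strict all-four intersection is selectable and is
provably a subset. Protection coverage uses current-scenario ranges; gap
species are covered ≤ 20% (boundary inclusive, with a 10⁻⁹ tolerance on
the ratio), severely underprotected < 5%.

## The synthetic basin

The generator emulates the statistical structure of an arid,
mountain-fringed basin rather than any specific geography:

- **Terrain**: flat southern desert plains, a steep mountain front, and a
  high northern plateau (monotone tanh ramp to ~3200 m plus smoothed
  random relief). This shape is load-bearing: plains are thermally dense
  (many cells per °C) while the front is sparse, so a warming-driven
  upslope shift of a lowland thermal band is a genuine area contraction,
  and the plateau provides an *observed* too-cold region that warming
  opens up.
- **Climate**: temperature = 22 °C − 6.5 °C/km lapse − 3 °C meridional
  gradient + smooth noise; precipitation = orographic term + an
  independent west–east moisture gradient + smooth noise. The independent
  precipitation structure keeps temperature and precipitation below the
  |r| = 0.8 screen so both niche axes survive screening, while their
  elevation correlations keep the designed signs (corr(DEM, T) < 0,
  corr(DEM, P) > 0 by construction). Two deliberately collinear
  temperature layers exercise the screen itself.
- **Future scenario**: an elevation-dependent temperature increment
  (lowlands up to 1.2×, ridge tops 0.8× of `warming_delta`, default
  2 °C) and a uniform precipitation scaling (default +5%). The null
  scenario (both zero) reproduces the current stack exactly.
- **Rivers and lakes**: steepest-descent walks on smoothed terrain from
  mountain-front headwaters, carving through closed pits and terminating
  only at the basin's lower edges; distance layers by exact Euclidean
  distance transform on cell centers. One mountain and one lowland lake
  keep distance-to-lake from being an elevation proxy.
- **Land use and threats**: cropland/urban occupy low, near-river cells;
  roads connect urban patches; threat rasters derive from these classes
  with typical weights/decays; the future map lets agriculture creep into
  adjacent low cells.
- **Species**: 16 by default — half lowland riparian (narrow warm thermal
  niche on the foothill fringe plus a river-distance response; designed to
  contract), half montane (cold-limited at the plateau edge plus a
  wet-side moisture affinity; designed to expand). Truth suitability is
  the product of Gaussian responses rescaled to [0, 1] (both scenarios on
  the current-scenario scale, so the designed sign reflects an absolute
  habitat change), with a population-viability floor: relative suitability
  below 0.45 is truly unoccupied. The floor encodes that rare-plant field
  surveys record persisting populations, not marginal sink habitat;
  without it, pseudo-absence contamination caps achievable model skill
  well below what such studies report. Two lowland species are
  dispersal-limited western endemics whose future field is a designed
  12-cell eastward translation of their current field — a known-truth
  scenario for the centroid-shift machinery, excluded from sign-recovery
  scoring.
- **Occurrences**: cells drawn without replacement with probability
  proportional to truth suitability, points uniform within cells;
  per-species counts ~U{30..48} so the default basin carries a total
  (~620 records) matching the record density such field campaigns yield.
- **Protected areas**: three circular reserves biased to the mountains,
  sized for a 12.87% protected fraction.

What passing tests show — and what they do not: the recovery tests
establish that the *pipeline machinery* (screening, ensemble, gating,
thresholding, stacking, overlay geometry) faithfully propagates a known
signal of realistic magnitude through every stage. They do not establish
robustness to spatial sampling bias, detection error, niche
non-stationarity, dispersal limitation, or biotic interactions — none of
which the generator emulates. Recovery is stochastic: at the default
conditions the designed CSH sign is recovered for ≥ 90% of species and
both stratum-level diversity predictions hold, but individual seeds can
fall below that for species whose designed change is small relative to
model estimation noise.

## Determinism and problem sizes

A single base seed fans out to landscape, niche, per-species and
per-repetition seeds; every stochastic component takes an explicit
generator seed. Report tables contain no timestamps, so identical
configurations produce byte-identical tables; wall-clock provenance is
written separately. Default problem sizes — a 120×120-cell basin,
16 species, 3 members × 10 repetitions — run the full chain in well under
a minute on one core; oracle-equivalence checks use 12–24-cell rasters
and ≤ 12-tip trees where brute force is exact and fast.

## Known limitations

- The ensemble ships three member families; the plug-in contract accepts
  more, but MaxEnt-style feature tuning is deliberately out of scope.
- max-TSS binarization with few validation presences is noisy; the pooled
  threshold mitigates but does not remove this.
- The InVEST-style model omits per-threat spatial-weight rasters and
  cumulative-threat capping variants; sensitivity tables are inputs, not
  calibrated.
- The deviational ellipse assumes basin-scale extents; do not use it for
  continental ranges.
- No reprojection: all inputs must already share one geographic grid.
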