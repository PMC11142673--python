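# Methods

This note documents the models and procedures implemented in
`corridorscape`, the parameter defaults and why they hold, the numerical
conventions, and what the synthetic landscapes do and do not emulate.

## The corridor model

The analysis treats climate adaptation as an elevational connectivity
problem: species in lowland protected areas will need routes to
higher-elevation habitat as climates warm, and intact montane forest is
the candidate refugium. A corridor is therefore a least-cost path from a
lowland reserve to a nearby montane forest patch over a structural
conductance surface, plus a fixed-width swath around it.

**Assumptions.** Movement cost depends only on land cover and forest
biomass (structural connectivity), not on topography or climatic
similarity along the route — appropriate for multi-decadal range shifts
rather than individual movements, and unavoidable when no single focal
species defines the surface. Conductance is isotropic and static. All
geometry is planar; inputs must share one metric, equal-area projection.

## Node selection

* **Cleaning.** Duplicated reserve geometries (normalized-WKB identity,
  first kept), "proposed" records, 'UNESCO-MAB Biosphere Reserve'
  designations, and records with unreported area are removed; marine
  reserves are clipped to a land polygon and their land portion kept
  (records with no land portion are dropped). When no land polygon is
  available, marine geometries pass through whole with a warning.
  Cleaning is idempotent.
* **Start nodes**: cleaned reserves with polygon area ≥ 5 km² and mean
  elevation ≤ 500 m. Both boundaries are inclusive: "≤ 500 m" is the
  phrasing used consistently for the lowland band, and ≥ holds for areas.
  Area comes from the polygon geometry in the working projection; the
  `reported_area` attribute only feeds the cleaning rule. Each start node
  is one interior representative point (guaranteed inside, computed on
  the largest part of a multi-part geometry).
* **End patches**: connected components — explicitly 8-connectivity — of
  cells that are forest *and* have integrity ≥ `integrity_min`, kept when
  ≥ 5 km² and mean elevation ≥ 1500 m, protected or not. The integrity
  cutoff for "medium or high" forest integrity is a named configuration
  value; the default 6.0 is the lower edge of the medium band on the 0–10
  scale of the global forest-integrity product. It is a convention of
  this implementation, not a value with an external citation.
* **End points**: a hexagonal lattice of pitch `hex_spacing` (default
  3000 m; row spacing `pitch·√3/2`, alternate rows offset by half a
  pitch), anchored at the patch's lower-left bound so placement is
  deterministic, clipped to the patch; a patch catching no lattice point
  gets exactly one point (its interior point). The default pitch makes a
  minimum-size 5 km² patch yield a single point while point count grows
  roughly linearly with patch area.
* Elevation statistics (mean, range) for any polygon are computed over
  the DEM cells whose centers fall inside the polygon itself (not a
  buffered footprint).

## Conductance and routing

* Class conductances come from a user-supplied CSV
  (`class_code, conductance, is_forest`). The shipped `EXAMPLE_LOOKUP`
  (forest 1.0; shrubland 0.6; wetland 0.5; grassland 0.45; cropland 0.3;
  bare 0.2; built-up and open water 0.0) is **illustrative** — plausible
  for medium-large forest mammals, calibrated to no species.
* The forest-quality modifier is `m = min(b, 100)/100` with `b` in Mt C:
  0 at zero biomass, 1 at or above the 100 Mt C cap. It multiplies only
  forest-flagged classes, once (a provenance flag guards against double
  application).
* Categorical resampling to a coarser grid (for 10 m-class inputs) takes
  the per-block modal class, ties broken toward the lowest class code;
  the factor must be an integer.
* Graph: nodes are cells; edges join 8-neighbors (4 available by config);
  the step cost is `d / ((c_i + c_j)/2)` with `d` the cell size (×√2 on
  diagonals). The arithmetic-mean edge rule matches the convention of the
  standard least-cost tooling. Zero-conductance cells are hard barriers
  with no incident edges, not epsilon-cost cells, so routes can never
  cross water or built-up when the lookup assigns 0.
* Each start is paired with its 5 nearest end points by Euclidean
  distance (ties by end-point id); when fewer exist, all are used with a
  warning. Paths start at the representative point, not the reserve
  boundary. One Dijkstra tree per start serves all of its pairings
  (scipy's sparse-graph Dijkstra). Among cost-equal paths, the
  reconstruction prefers the lowest (row, col) predecessor — a backwalk
  on the exact distance field with a 1e-9 relative equality tolerance —
  so outputs are byte-reproducible. A start/end point landing on an
  impassable cell snaps to the nearest passable cell within 5 cells;
  beyond that it is an error. Unreachable pairs are recorded with an
  explicit status, never silently dropped.

## Corridor metrics

All corridor variables except length are computed on the 1000 m buffer
(round caps/joins) of the polyline: elevation range, percent protection,
overlapping non-marine protected areas, overlapping KBAs, mean biomass,
and countries crossed (the buffer, not the bare polyline, for consistency
with the other buffer variables; the primary country is the largest
overlap, ties to the lowest id). Zonal statistics use the **cell-center
rule** — a cell belongs to a zone iff its center is inside the polygon —
which is simple and exactly checkable against a brute-force loop; users
of area-weighted conventions will see small differences at patch edges.
Percent protection intersects the buffer with the *union* of reserves, so
overlapping reserves never double-count. Mean biomass averages over all
buffer cells, zeros off-forest included, matching the semantics of the
biomass layer as used by the conductance modifier; a forest-only option
exists but is off by default.

## Priority index

The default feature set expresses the design premise — short, protected,
well-forested corridors linking large lowland reserves to large, intact,
elevationally diverse highland patches, ideally through recognized
biodiversity areas: corridor length (inverted by negating the raw value
before standardization; the sign does not affect the index but keeps
loadings interpretable), corridor elevation range, corridor protection,
overlapping protected areas, overlapping KBAs, corridor mean biomass,
start area, start elevation range, end area, end elevation range, and end
protection. The list is fully user-overridable.

Variables are screened pairwise: when |Spearman ρ| ≥ 0.7 (configurable;
chosen consistent with dropping pairs observed near 0.7–0.8), the
designated variable of the pair is dropped — by default the corridor
protected-area count (keeping length) and the end-patch area (keeping end
elevation range). Variables constant over the corridor set are dropped
with a warning before standardization, which uses the n−1 divisor. The
PCA is an eigendecomposition of the correlation matrix (equivalently the
covariance of the z-matrix); loadings carry a fixed sign convention
(largest-magnitude entry positive) for reproducibility; components beyond
the matrix rank are dropped with a warning.

The index is the Euclidean distance from the origin in the space of the
first three component scores; classes are low [0, 2), medium [2, 4]
(inclusive both ends — the "< 2 / 2–4 / > 4" banding forces this), high
(4, ∞). Three components and the 2/4 cuts are the analysis defaults,
retained here as named configuration values.

**Caveat.** Distance from the origin is direction-blind: a corridor
extreme on the *unfavorable* side of a component also scores high. The
index is implemented exactly as defined; the guard in this package is the
designed-winner recovery test (a constructed landscape whose best
corridor must attain the top index), not any re-weighting. Real analyses
should inspect the loadings before interpreting high scores.

## Group statistics

Spearman's ρ is the Pearson correlation of mid-ranks (tie-corrected),
with the t-approximation on n−2 degrees of freedom. Kruskal–Wallis uses
the tie-corrected H with the χ² approximation on g−1 df; an all-tied
sample returns H = 0, p = 1. Dunn's pairwise z statistics use pooled
mid-ranks with the tie correction
`S = N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p-values, and Holm
step-down adjustment across all pairs. Dunn runs only when the omnibus
p < 0.05 (configurable; a force flag overrides). All p-values are
asymptotic — appropriate for the group sizes of a regional corridor set;
exact small-sample p-values are out of scope.

## Synthetic landscapes

The generator emulates the *structure* the pipeline assumes, not any real
region: a west–east elevation ramp calibrated so that about
`lowland_fraction` of the profile sits at or below 500 m (clipped, not
rescaled, so the calibration survives the added smoothed noise); a
fragmented forest mosaic thresholded at the exact `forest_fraction`
quantile of a smoothed suitability field with a highland bias (so montane
forest exists) and a carved two-cell matrix gap (so corridors always face
at least one barrier); biomass ~ Normal(70, 30) Mt C truncated at zero on
forest cells and zero elsewhere, putting a visible share of cells above
the 100 Mt C cap; an integrity field smooth enough to carve patches
rather than speckle; and polygon tables in which rows 0–5 of the reserve
table are fixed pathological fixtures (a duplicated pair, a proposed
record, a marine record straddling the extent edge, a UNESCO-MAB record,
an unreported-area record) with generic reserves mixing sizes and
elevations on both sides of the 5 km² and 500 m thresholds. Countries
partition the extent by Voronoi cells of random seeds. Every generator is
a pure function of (config, seed).

Defaults describe a 30 km × 30 km mountain front at 100 m resolution
(300×300 cells), 40 reserves, 12 KBAs, 3 countries. At this extent a
generated world typically yields ~15–20 start nodes, 1–6 montane patches
and ~10–25 end points, about a hundred corridors, and first-three-PC
variance explained around 0.6–0.75. Occasionally a world holds *no*
qualifying montane patch (as real political units sometimes do); the
pipeline then stops with an explicit error, and batch drivers skip to the
next seed.

What the synthetic worlds do **not** emulate: real spatial
autocorrelation ranges or class frequencies, geodesy (everything is
planar), the 10 m native resolution of real land-cover products
(generation happens at working resolution; a fine-resolution option
exists only to exercise the resampler), or realistic reserve shapes
(convex blobs). Passing tests therefore demonstrate the *correctness of
the computations* under controlled conditions, not the ecological
validity of any particular real-data result.

## Scale of the shipped computations

The validation suite runs at desk scale by design: the pairing-arithmetic
study uses a 300×300 grid with 475 lattice-packed start reserves (the
density of a real lowland protected-area estate, overlaps included);
oracle comparisons use 20×20 and 4×4 grids where brute force is exact;
the end-to-end determinism check uses a 120×120 world. Regional results
computed from continental GIS data (per-country corridor counts and
medians, a specific variance-explained figure, specific class counts)
depend on those data and are not targets of the synthetic runs.

## Numerical conventions

ASCII-grid I/O uses `%.17g` formatting (exact float64 round trip).
CSV outputs use `%.10g`. The manifest contains configuration, seed, and
per-stage counts only — no timestamps — so identical runs are
byte-identical. Eigenvalues are clipped at zero against roundoff;
rank is assessed at 1e-10 relative tolerance. Invalid input polygons are
repaired with a zero-width buffer when possible, else rejected listing
feature ids.
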