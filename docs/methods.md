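# Methods

## Model

`popaccess` measures the spatial accessibility of a population to point
destinations with a spatial-interaction (gravity) model. Each demand unit
("block") *i* has a centroid, a population count `Pop_i`, and a nested
hierarchy path (block → tract → county → state, FIPS-style id strings).
Each destination ("outlet") *j* has a location and an optional positive
size weight `w_j` (default 1: every destination equally attractive).

For every populated block and every distance engine, the block's choice
set is its `n` nearest destinations (default `n = 7`, a conventional size
for a realistic consideration set) with distances `d_ij`. From the choice
set:

* gravity accessibility index `A_i = Σ_j w_j / d_ij^β`
* Huff choice probability `P_ij = (w_j / d_ij^β) / A_i` — the probability a
  resident visits destination *j*; decreasing in distance but never zero
  inside the choice set, reflecting that people do not always pick the
  nearest option
* population-weighted distance `PWD_i = Σ_j P_ij d_ij` — the expected
  travel cost under Huff behaviour

The distance-decay exponent `β > 0` defaults to 1 (inverse-distance decay).
At `β = 1` with unit weights, `PWD_i` is the harmonic mean of the choice-set
distances, hence `PWD_i · A_i = m` exactly for a set of size `m`, and
`min d ≤ PWD_i ≤ mean d ≤ max d`. These identities are enforced in the test
suite and are useful run-time sanity checks on real data.

Area-level measures are population-weighted means over an area's included
blocks: `PWA_k = Σ Pop_i A_i / Pop_k` and `PWD_k = Σ Pop_i PWD_i / Pop_k`.
Weighted means nest, so aggregating blocks directly to a county equals
rolling up block → tract → county; the package asserts this to 1e-9
relative error. `PWA` is reported in reciprocal metric units (1/mile or
1/minute); it has no conventional unit label in the literature, which is
one reason the more interpretable `PWD` (miles/minutes) is computed
alongside it.

## Distance engines

1. **Straight-line** ("Euclidean" in the field's loose usage): great-circle
   distance by the haversine formula on a sphere of mean radius 3958.7613
   miles. An ellipsoidal geodesic would differ by < 0.5 %, far below the
   contrasts the metrics are designed to expose; the radius is a parameter.
   In planar mode, coordinates are miles on a flat plane and the engine is
   ordinary Euclidean distance.
2. **Driving distance** and **3. driving time**: shortest-path cost on a
   street graph whose edges carry a length (miles) and a travel time
   (minutes); when the edge table supplies speeds instead of times,
   `time_min = 60 · length_mi / speed_mph`. The graph is undirected by
   default (one-way handling is data we do not model; a directed mode
   exists). Points are snapped to their geodesically nearest *node* —
   edge-projection snapping would be finer-grained, but node snapping is
   simpler and its error is bounded by the edge length, which is small on
   the dense grids the generator emits. A point with no node within the
   maximum snap radius (default 1.0 mile) is *excluded from network
   metrics* — a recorded outcome mirroring how blocks with no street access
   are handled in national studies — while keeping its straight-line
   metrics. Consequently the three engines can have different denominators;
   a `common_support` flag restricts all metrics to the common block set
   when strict comparability matters.

The network k-nearest query is an own Dijkstra with early termination: the
search stops once `k` destinations are settled and the frontier cost
passes the k-th best (ties at equal cost are still collected and broken by
destination id). Exhaustive single-source shortest paths followed by a
top-k sort is the reference semantics, and the tests assert equality
against an independent shortest-path oracle on random graphs. The
straight-line k-nearest search is an exhaustive vectorized scan; an
optional square-tile index only prunes candidates when its buffer provably
certifies the answer (otherwise it falls back to the full scan), so it can
accelerate but never change results.

## Numerical choices

* **Zero-distance floor.** A destination coincident with a block centroid
  (possible after node snapping) would make `A_i` infinite, so every
  distance is floored at `ε` (default 0.01 metric units) before any
  formula; floor events are logged. The floor is a *length*: the exact
  scaling covariance (all lengths × c ⇒ every PWD × c, every A ÷ c at
  β = 1) therefore holds when ε — and the snap radius — are scaled with the
  geometry, which is how the scaling tests are phrased. With ε held fixed,
  a floored distance breaks exact covariance by construction.
* **Tie-breaking.** Equal distances are broken by ascending destination id;
  equidistant snap candidates by ascending node id. All outputs are
  deterministic given inputs, and re-runs are byte-identical.
* **Short choice sets.** Configurations with fewer than `n` reachable
  destinations keep their smaller set (`m < n` recorded) rather than being
  dropped; `A`, `P`, `PWD` are computed over the `m` available terms. An
  empty set (no reachable destination at all) yields undefined metrics and
  an exclusion flag.
* **Degenerate summaries.** A class with a single county reports sd = 0
  with a `sd_degenerate` flag (keeping tables rectangular); an empty class
  reports count 0 and NaN statistics. Correlations are pairwise-complete
  over exclusions and computed at block level by default.
* **Serialization.** Delimited text is canonical (floats at 6 significant
  digits on disk, full precision in memory); GeoJSON is available for
  point layers.

## Synthetic geography

Licensed national inputs (point-of-interest feeds, census block files,
routable street data) cannot be redistributed, so the generator emulates
their statistical structure on a seeded stream (identical seeds give
byte-identical tables):

* **Street grid**: `48 × 32` nodes at 0.5-mile spacing (a 23.5 × 15.5-mile
  region), 4-connected, hence connected by construction; each edge draws a
  speed class from {25, 45, 65} mph with weights {0.6, 0.3, 0.1}.
* **Hierarchy**: 24 counties tile a 6-column × 4-row grid across 3 states;
  2 tracts per county. Each county *column* carries one NCHS urban–rural
  class, most urban (1) in the west to most rural (6) in the east, with
  county attribute records (MSA membership, MSA population, principal-city
  flags) constructed so the classifier reproduces the intended class.
* **Blocks**: 720 blocks split evenly across counties, centroids uniform
  within a random tract rectangle. Populations are log-normal
  (μ = 3.5, σ = 1.2; median ≈ 33 at the rural baseline, mimicking
  heavy-tailed census-block populations) scaled by the county class
  multiplier (32, 16, 8, 4, 2, 1 for classes 1…6 — a ~30× metro→noncore
  density span). 2 % of blocks are forced to zero population to exercise
  the populated-block filter.
* **Outlets**: 200 destinations; a clustered fraction (default 0.85) is
  placed at a population-proportional block plus N(0, 0.15 mi) jitter, the
  rest uniform over the region. Clustering toward population is the
  mechanism that produces both the metro→noncore PWD gradient and the
  negative PWA–PWD correlation structure.
* **Island option**: `n_isolated_blocks` places blocks ~10 miles off-grid,
  beyond any snap radius, to exercise the network-exclusion path.

Planar mode is the default: the metric algebra is curvature-free and a flat
plane supports exact scaling tests. Geographic mode expresses the same
geometry in equatorial degrees, where the degree→mile conversion is
uniform.

**Layout rationale.** The stratified summary takes an *unweighted* mean of
county values within each class, so its seed-to-seed stability is governed
by the number of counties per class and by county size relative to the
7-nearest search radius. Early layouts with 2 counties per class (thin
vertical strips) showed the expected gradient on average but frequent
adjacent-class inversions: the class mean of two counties is noisy, and
strips narrower than the search radius let neighbouring classes smooth each
other out. The 6 × 4 county grid gives 4 counties per class at ~4-mile
county width, which keeps class means stable while preserving the
density-driven gradient; with it, the monotone class-1→6 gradient holds on
≥ 80 % of seeds and the correlation sign structure on essentially all.

**What the generator does not emulate**: realistic road topology (curves,
interchanges, one-ways), coastlines and empty land, spatially correlated
population surfaces within counties, destination size heterogeneity, and
national scale (720 blocks vs millions). Passing tests therefore certify
the *algebra, search correctness, bookkeeping and qualitative structure*
of the pipeline, not any particular empirical magnitude on real data.

## Problem sizes

Defaults were chosen so a full pipeline run takes well under a second and
the complete test suite (including 20-seed stability checks and 50-graph
oracle sweeps) runs in tens of seconds on one core, while remaining large
enough that every class, level, and exclusion path is populated. All sizes
are configuration, not constants; national-scale runs would use the same
code paths with the optional tile index and per-origin search caching.

## Known limitations

* Node-based snapping quantizes both origins and destinations to the grid;
  co-snapped pairs hit the ε floor, which dominates `A_i` for those blocks
  (real studies show the same behaviour as very small minimum PWD values).
* The undirected graph ignores one-way streets and turn restrictions;
  travel times are free-flow, with no congestion or time-of-day variation.
* Only power-law (inverse-distance) decay is implemented; exponential or
  Gaussian kernels and floating-catchment variants are out of scope.
* The Pearson comparison treats blocks as independent observations; no
  spatial autocorrelation correction is attempted.
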