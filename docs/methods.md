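# Methods

## Scope and units

All geometry is planar easting/northing in meters (British-National-Grid
style); there is no geographic coordinate support and no projection
handling. Graphs are undirected with strictly positive edge weights equal
to segment lengths. Every analysis is run per district and pooled
afterwards, so a district's results depend only on its own topology.

## Geometry and graph construction

Roads arrive as polylines (segment chains broken at bends and
intersections). Assignment to districts distinguishes three cases: fully
inside (assigned whole), crossing (cut at every boundary intersection, each
inside piece assigned to its district, the outside remainder discarded or
assigned elsewhere), and boundary-coincident (emitted once with both
district ids). Clipping delegates to shapely; cut points are exact
line/edge intersections, and inside-piece lengths satisfy a 1e-9 relative
conservation law that the test suite asserts on random cases.

Nodes are welded by coordinate within 1e-6 m. This tolerance must weld the
float-identical cut points that clipping produces on both sides of a
border, while staying far below any road-length scale; the same tolerance
classifies "on boundary" points and merges co-located snapped POIs.

Connectivity pathologies are classified with two thresholds of our own
choosing (in real datasets such cases are rare and are resolved by hand;
the classifier automates the triage): a component is
"small" below 5% of the district's nodes, and two components "nearly touch"
when their minimum node gap is under twice the 95th-percentile edge length
(a proxy for the block pitch that is robust to the many short bend-induced
segments; the median is not). One main component plus small detached ones
reads as a hamlet; two large near-touching components read as a boundary
connector; several large mutually distant components read as islands.
Resolution strategies: move the minimal foreign bridging segment in
(connector), split the district per component (hamlet), or drop the
district (islands). The pipeline resolves connectors first so that the
stray fragment leaves the neighbouring district before that neighbour is
considered for splitting.

## Snapping and overlay

Snapping is defined as the exhaustive minimum of point-to-segment distance
over all of a district's edges; the KD-tree over sub-segment midpoints only
bounds the candidate set and is exact by construction. Ties break on the
smallest edge id. The snap records the arc-length fraction along the full
polyline, so inserting the POI as a graph node later splits the edge with
exact length conservation (children are offset differences, not re-measured
geometry). POIs are snapped only within their resolved district; an outlet
near a border that is physically closer to another district's road keeps
its administrative assignment, and this is a documented limitation.

Small-area overlay repeats the district splitting logic at area boundaries
after snapping; snapped POIs are re-attached to the child edge containing
their offset, which preserves per-category counts. Deprivation tertiles use
order statistics — `q1` is the `ceil(n/3)`-th and `q2` the `ceil(2n/3)`-th
sorted score — with inclusive upper boundaries, so per-tertile counts
differ by at most the remainder of `n/3`. Degenerate inputs (all scores
equal) raise rather than fabricate boundaries.

## Distance queries

Nearest-school distances run one multi-source Dijkstra with all school
nodes as zero-distance sources (equivalent to a virtual super-source);
nearest-other-outlet distances run one Dijkstra per outlet that terminates
on the first settled other-outlet node. Both run on CSR adjacency through
numba-jitted kernels with a manual binary heap; equal-length path ties are
detected at 1e-12 relative tolerance, which ties exactly for integer
weights (whose float sums are exact) and never fires spuriously on
continuous jittered lengths. Unreachable targets report +inf and are
excluded from curves with their count logged. Buffer curves histogram
distances over (prev, edge] bins with a dedicated spike bin for exact zeros
(co-located POIs) and an overflow bin past 600 m, the largest value in
current zoning policy.

## Centralities and their approximation

Betweenness is accumulated per source by Brandes' dependency recursion and
summed over ordered pairs (an undirected pair contributes twice; only
ranks are consumed downstream, so the convention only needs to be fixed and
is cross-checked against networkx at half scale). Degree-1 nodes are
removed in one single pass before betweenness — no shortest path between
two non-leaves crosses a leaf — and reported with centrality 0. The pass is
deliberately not iterative (chains are not consumed); an iterative switch
exists (`prune_leaves(iterative=True)`, CLI `--prune-iterative`). Interior
betweenness computed on the pruned graph excludes leaf-terminated paths;
this matches the procedure the analysis follows and deviates from the
textbook definition, which matters only if absolute values, not ranks, are
compared. Closeness is computed on the full graph within each connected
component (scipy's C Dijkstra); isolated nodes report 0.

The pivot approximation samples `k` sources uniformly without replacement
from a single seeded generator. Betweenness is estimated as `n/k` times the
summed pivot dependencies. Inverse closeness is estimated per component as
`Ŝ(u) = (n_C/k_C)·Σ_i d(p_i, u)` over the `k_C` pivots landing in `u`'s
component (components without pivots report 0 with a warning). Both
estimators are unbiased and reduce exactly to the full computation at
`k = n`; the suite asserts this identity at 1e-9 relative. The `n/k`
closeness scale (rather than `(n-1)/k`) is required by that identity.
Error thresholds are Hoeffding-type: a single pivot's contribution is
bounded by `n-2` (betweenness dependency) or the component diameter
(closeness sums), giving `P(err > ε·n·(n-2))` resp. `P(err > ε·n·Δ)` at
most `2·exp(-2kε²)` per node. The defaults `k = 109`, `ε = 0.05` are an
operating point at which district-scale error is small while cost stays
near a hundred source computations; the sweep utility tabulates empirical mean/max error and exceedance against this
bound for any `k` list.

Centrality values are indices, not magnitudes, so correlation uses
average-tie fractional ranks (which Spearman requires to be well defined).
Outlets are re-assigned to their Euclidean-nearest *node* for this analysis
(ties to the smallest id), and Pearson/Spearman correlations are computed
per district over all non-pruned nodes with zero counts included; constant
inputs raise an undefined-correlation error and the district is skipped.

## Scaling fits

The discrete buffer histogram becomes a continuous curve as the empirical
CDF at bin upper edges, with the zero spike merged into the first positive
edge so the grid stays log-safe; leading empty bins are dropped under a log
y-axis since they carry no information there. OLS (scipy `linregress`) runs
on the transformed coordinates for all four axis combinations; R² is the
squared correlation and the p-value is the slope's t-test, reported per fit
without multiple-testing correction. Fits are produced overall and per
tertile; strata that are empty or all-zero are skipped with a log entry.

## The synthetic generator

Districts are unit squares (default five of 18 km side) in a row. Roads are
a jittered square grid (400 m pitch, ±15% jitter); nodes sit half a pitch
from every border so only deliberate crossings exist, and every grid row
crosses every interior border. A configurable fraction of links (default
30%) is emitted as a chain of three segments with two off-axis bend
vertices — matching how road files break a segment at every bend — which is
what brings the mean node degree into the observed 2–3 range; 10% of nodes
grow a dead-end spur, so leaf pruning removes roughly a tenth of nodes.
Deprivation is a linear west-east gradient (scores 5–45, area noise SD 2)
over 3×3 sub-areas per district.

Outlet clustering is a sequential paired process chosen because it directly
controls the acceptance statistic: each outlet is clustered with
probability `f` (default 0.8); clustered outlets are placed in pairs — the
first member uniformly (length-weighted) on a fully-inside road, the second
on the same road within 0.95·r arc distance (default r = 120 m), 15% at the
identical spot — so every clustered outlet has a neighbour within `r` *by
construction* and the realized fraction is binomial around `f`. Schools are
placed independently with a minimum-dispersion rejection step (default
800 m). A Matérn-style cluster process would emulate geography more richly
but would control the fraction-within-r statistic only indirectly.

What the generator does not emulate: real street hierarchies (motorways
versus lanes), non-convex district shapes, density gradients between urban
and rural areas, and cross-district outlet pairs (pairs always share a
road). Passing tests therefore demonstrate that the *pipeline machinery* is
correct and that generative parameters are recovered — not that any
particular capture fraction or exponent generalises to real geography.

Measurement beats bookkeeping wherever both exist: the recovered pair
fraction is measured by the full snap → insert → Dijkstra chain and
compared against the generator's record, at tolerance 0.03 (binomial noise
plus the small uniform-baseline contamination of unpaired outlets, about
+0.005 at the default road density).

One structural effect worth knowing: placing outlets uniformly *on the
streets* (length-weighted) is not independent of topology — junction nodes
capture systematically more nearest-node assignments than short-edged bend
nodes, inducing a mean betweenness-rank correlation around +0.08. The null
correlation control therefore places outlets uniformly over the district
*area*, which is independent of topology by construction; the clustered
default placement shows correlations well inside ±0.1 either way.

## Problem sizes and determinism

Default study conditions: 5 districts × ~4,600 nodes / ~6,800 edges, 2000
outlets, 300 schools. Oracle-based checks run on purpose-built sizes:
exhaustive path enumeration at n ≤ 12, cubic path-counting centralities at
n ≤ 40, estimator bounds on a ~2,000-node single-district grid with 100
pivot seeds, clustering recovery over 20 world seeds. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; pipeline
manifests record the config hash and seed and contain no timestamps, so
identical configurations produce byte-identical output bundles.

## Known limitations

- Distances never cross district borders (per-district processing); the
  count of border-adjacent outlets is visible in the logs but no correction
  is applied.
- Duplicated boundary segments appear in both adjacent district graphs;
  national tallies deduplicate by parent road id, but per-district edge
  counts intentionally double-count them.
- The planar-graph O(n) shortest-path alternative is out of scope; Dijkstra
  is used throughout.
- Shapefile ingest is not implemented; GeoJSON/CSV are the native formats.
- The boundary-connector resolver only finds single-segment bridges, which
  is what the injected pathology produces; multi-segment detours would
  need a broader search than the single-bridge case this addresses.
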