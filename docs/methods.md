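# Methods

This note records the models, estimators and numerical choices behind the
package, and what the synthetic generators do and do not emulate. It makes
no empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Volume laws

For a node `n` of a connected graph, the ball `B_n(r)` is the set of nodes
whose shortest-path distance from `n` is at most `r`; its *volume* is
`|B_n(r)|`. Distances may be hop counts (`unweighted`), stored edge weights
(`native`), Euclidean edge lengths recomputed from node coordinates
(`euclidean`), or travel times (`travel_time`). Two parametric families are
fitted to the mean volume over sampled centres:

- polynomial: `v(r) = 1 + k · r^d`, `k > 0`, `d > 0`;
- exponential: `v(r) = 1 + a · (b^r − 1)`, `a > 0`, `b > 1`.

Both satisfy `v(0) = 1` exactly: a ball of radius 0 is its centre. The
exponential parameterization is chosen so a perfect binary tree measured
from its root, `|B(r)| = 2^(r+1) − 1`, corresponds exactly to `a = 1,
b = 2` (verified to machine precision in the tests).

## Spatial network model

Nodes are `n` points drawn uniformly from the unit hypercube `[0,1]^dim`
(coincident points are rejected and resampled). With `δ(p)` the distance
from `p` to its nearest other point, the model places a directed edge
`(n1, n2)` whenever

```
dist(n1, n2) ≤ ρ · δ(n1),     ρ > 1,
```

ties included, so the rule is invariant under global rescaling of the
point cloud. All analyses use the associated undirected graph. The rule is
evaluated with a k-d tree (nearest neighbour via `query(k=2)`, candidates
via per-point ball queries of radius `ρ·δ`); an O(n²) brute-force oracle
in the test suite checks exact edge-set equality on hundreds of random
point sets.

Defaults `ρ = 1.8` and `n = 10 000` are the package's study conditions:
`ρ = 1.8` yields a sparse, largely connected planar-like graph with ~2.4
edges per node in 2D, and `n = 10 000` gives two decades of usable radii
before saturation while keeping a full profile under ~20 s on one CPU.

### Hierarchical variants

A hierarchy spec lists strictly decreasing layer sizes `|N_0| > |N_1| > …`;
layer 0 is the full point cloud and each deeper layer is a uniform random
subset of the previous one. Each layer is wired independently by the edge
rule (deeper layers are sparser in space, so their nearest-neighbour
distances — and hence their edges — are longer-ranged), and the edge sets
are unioned. For a fixed seed, all specs share the same base points and
nested subsets, so adding a layer is a controlled intervention: the
layered graph's edge set strictly contains the base graph's.

The weighted variant assigns each layer-`i` edge the weight
`w_i × Euclidean length` with user-supplied positive `w_i`; when an edge
appears in several layers the minimum weight wins (the faster service).
This emulates express links: long but cheap connections that shrink
network distances at large scales.

What these generators emulate: the local, distance-bound wiring of
infrastructure networks (roads, rails, supply lines) and the overlay of
faster long-range services on top of them. What they do not emulate:
degree heterogeneity beyond what geometry induces, directed flows,
capacity, temporal variation, or any correlation structure in node
placement (points are i.i.d. uniform; the hypercube boundary thins
neighbourhoods at the faces, which biases fitted dimensions slightly low).

## Volume profiles

A profile samples up to 10 000 centres without replacement from the
largest connected component and runs one shortest-path sweep per centre
(`scipy.sparse.csgraph.dijkstra`, breadth-first search in unweighted mode,
in chunks of 512 sources); per centre, sorting the distance array and
`searchsorted` against the radius grid yields all ball volumes at once.
The profile records per-radius mean and standard deviation (ddof = 1) and
the network (component) size as the saturation ceiling.

The radius grid comes from a 200-centre pilot: `r_max` is where the pooled
distance distribution reaches 95 % of the component, i.e. balls nearly
saturate; unweighted grids use integer radii (with a minimum `r_max` of
8), weighted grids 64 uniform values. Explicit radii or centres can be
supplied instead — the tests use fixed centres for closed-form cases
(tree root) and shared centres for hierarchy comparisons.

## Fitting and classification

Fits are weighted least squares on the natural scale with weights
`1/sd²`; radii with zero sd (the deterministic `r = 0` point and tied
small radii) get the smallest positive in-window sd as a floor. The fit
window runs from the first radius with mean volume ≥ 5 (below that,
discreteness dominates) to the last with mean ≤ 0.5 × component size
(beyond that, saturation bends every law), and must contain ≥ 4 points.
Optimization uses `scipy.optimize.least_squares` (trust-region reflective,
analytic Jacobians) initialized from a log–log regression, with five
seeded random restarts; standard errors come from `inv(JᵀJ)` at the
optimum. `classify_law` fits both families and returns the smaller
weighted residual sum of squares, or `"neither"` if every family's
log-scale RMSE exceeds 0.2 — a relative-error yardstick: 0.2 in log space
is ~22 % typical multiplicative misfit, far beyond sampling noise at
10 000 centres yet loose enough to tolerate window-edge curvature.

## Box counting

The Minkowski–Bouligand dimension of the embedded node set (or edge set)
is estimated from counts of occupied boxes on 16 geometrically spaced
sides between `diag/2` and `diag/256` (`diag` = bounding-box diagonal).
Boxes are half-open, so boundary points count once; counts are averaged
over 500 uniformly random grid translations. The `edges` variant
discretizes each edge into points spaced at most `smallest_side/25`
apart, so no examined box can be crossed undetected.

The regression `log(count)` vs `log(side)` keeps only the clean scaling
regime, with both cutoffs derived rather than tuned:

- **Coarse end** — sides above `diag/16` are excluded. For an extent `L`,
  counts grow like `(L/s + 1)^d`; the boundary `+1` flattens the log–log
  slope whenever `s` is not ≪ `L`.
- **Fine end (nodes)** — sides where the mean count exceeds 0.2 × the
  node count are excluded. With `N` points thrown into many boxes,
  occupancy is approximately Poisson with mean `λ`; the elasticity of
  the expected occupied-box count with respect to `1/s` is damped by the
  factor `λ/(e^λ − 1)` (≈ 0.96 at the cutoff, deteriorating quickly
  beyond), because counts saturate at the point total.
- **Fine end (edges)** — the discretized edge set is dense, so the
  ceiling is instead the total number of boxes covering the bounding
  region, with cutoff 0.95.

An explicit `fit_window=(s_max, s_min)` can override the automatic
window. This matters when comparing the two variants: on a shared window
that reaches below the node-occupancy scale, node counts saturate while
edge counts keep growing, so the node variant estimates a lower dimension
— the expected signature of edges filling the space between nodes. With
each variant fitted on its own automatic window the regimes differ and no
such ordering is implied.

## Transport schedules

GTFS `stop_times.txt` is read with pandas. The traversal time of a
consecutive stop pair in a trip is the difference of stop *midpoints*,
`mean(arrival, departure)` — splitting dwell time evenly between the
incoming and outgoing edges. Times follow the GTFS convention (hours may
exceed 23 for after-midnight service) and are kept in minutes. Trips with
duplicate stop sequences or non-monotone midpoints are dropped with a
warning; repeated stop pairs across trips are merged by mean (default) or
minimum traversal time. Stop coordinates, when complete, become node
coordinates `[lon, lat]`.

## Known limitations

- In 1D the model fragments: a pair of consecutive gaps can each fail the
  edge rule (probability ≈ 0.13 per side at `ρ = 1.8`), so the largest
  component of a 10 000-point instance holds only a few dozen nodes.
  Fitted dimensions are correspondingly noisy, though still near 1.
- Uniform sampling in a bounded cube thins neighbourhoods at the faces;
  fitted volume-law dimensions in 2D/3D land a few percent below the
  embedding dimension (≈ 1.86 and ≈ 2.6 at the study scale).
- Standard errors from `inv(JᵀJ)` ignore the correlation between volumes
  at nearby radii (the same centres feed every radius), so they
  understate parameter uncertainty; the tests therefore check seed-to-seed
  stability directly.
- The box-count estimator assumes an approximately uniform measure; it is
  a sanity instrument for embedded geometry, not a multifractal analysis.
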