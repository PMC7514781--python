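# Methods

This note documents the models implemented in `braingen`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Network construction

A subject or group is represented as a simple undirected binary graph over
a fixed node set of atlas regions. Construction follows the standard
functional-connectome recipe: Pearson correlation between regional time
courses, Fisher r-to-z transform (z = arctanh r) for variance
stabilization, group averaging, then a strict threshold (edge iff value
> θ). Two conventions are worth making explicit:

- **Strict inequality at θ.** Ties are excluded; raising θ never adds an
  edge (the edge sets are nested in θ).
- **Scale of θ.** Because arctanh is strictly increasing, thresholding the
  z-scale average at arctanh(θ) equals thresholding the r-scale average at
  θ. The CLI defaults to the z scale (`--scale z`) and exposes `--scale r`;
  a property test asserts the equivalence for matched thresholds.
- Negative correlations are not absolute-valued; they simply fall below any
  positive θ.

## Similarity scores

Five classical neighborhood indices (CN, PA, JC, AA, RA; natural log in
AA) and the mutual-information score S_MI are implemented both as per-pair
operations and as vectorized all-pairs matrices (dense linear algebra; the
two routes are cross-checked in tests). Conventions:

- Jaccard with an empty neighborhood union is 0.
- The prior link probability p(L¹) = 1 − C(|E|−k_m, k_n)/C(|E|, k_n) is
  evaluated in log space via log-gamma; direct factorials overflow at
  connectome scale (|E| ≈ 600). C(a, b) = 0 when a < b, making p = 1.
- The conditional probability p(L¹|z) — the clustering coefficient of the
  shared neighbor z — is Laplace-smoothed to (2|Ez|+1)/(|Γz|(|Γz|−1)+2)
  inside the MI score, because a triangle-free neighborhood would otherwise
  give p = 0 and an infinite conditional self-information. The smoothing is
  confined to a single function; the raw value is available alongside.
- The per-neighbor information I(L¹; z) averages over *ordered* neighbor
  pairs m ≠ n with normalization |Γz|(|Γz|−1), which equals the unordered
  average by symmetry.
- All quantities (|E|, degrees, |Ez|) are read from the current graph
  state; nothing is cached across evolution events.

## Connection probabilities and ranking

P(u, v) = S(u, v)^γ · d(u, v)^(−η), with d the Euclidean distance between
region centroids in mm (no normalization — η absorbs the scale).

**Positivization of MI scores.** S_MI = −I(L¹|ω) is a log-probability and
can take either sign, so a power S_MI^γ is not directly defined. The
package exponentiates first: P = exp(S_MI)^γ · d^(−η) = p(L¹|ω)^γ · d^(−η).
This keeps the exact power-law form with a probability base, preserves the
score ordering for every γ > 0, and sends pairs with an isolated endpoint
(S_MI = −inf) to P = 0. An affine shift (S − min S + 1) was evaluated as an
alternative and rejected: it compresses the scores into a narrow band, the
distance term then dominates the ranking for small γ, and whole regions of
the (γ, η) lattice collapse onto bit-identical evolutions, which makes
parameter fitting ill-posed.

Ranking for evolution: absent pairs sorted by P descending (additions),
present pairs ascending (deletions). Ties in P break lexicographically on
the (min-id, max-id) pair; among P = 0 pairs, distance decides first
(shorter preferred for addition, longer for deletion) since the model
offers no signal there.

## Evolution engine

Given quotas α (additions) and β (deletions), each event first recomputes
S and P on the current graph, then applies the top-ranked eligible action.
The add/delete order is randomized: an event is an addition with
probability remaining_α/(remaining_α + remaining_β), which spends both
quotas without dead iterations. A degree guard walks down the deletion
ranking past any pair in which either endpoint has only one remaining
connection, so no node is ever isolated; global connectivity is checked at
termination and reported (a warning), not enforced per event. Re-adding a
previously deleted pair is permitted by default (quotas count events); a
strict mode forbids reversals, making the final symmetric difference
exactly α + β pairs. Per-event full recomputation costs O(n³) worst case
and is deliberate — at n = 90 one event takes ~1 ms and correctness is
easier to audit than with incremental caching.

Randomness is a single integer seed owned by the engine; identical seeds
reproduce traces bitwise.

## Metrics and the similarity index

C is the mean local clustering coefficient (degree-<2 nodes contribute 0)
and T the global triangle/triple ratio — two different statistics, both
reported. L is defined only for connected graphs (an error otherwise, never
an average over infinities); Eglob treats unreachable pairs as zero
efficiency. Eloc is the mean over nodes of the global efficiency of the
neighbor-induced subgraph. Path-based metrics run on scipy's C BFS
(`scipy.sparse.csgraph`); the pure-Python networkx implementations serve as
independent oracles in the tests. Modularity M is the Newman Q of a seeded
Louvain partition (networkx), deterministic per seed; an
exhaustive-partition oracle is provided for graphs of ≤ 12 nodes.

SI = 1/Σξ over the six relative errors ξ = |x_syn − x_target|/|x_target|.
Larger SI is better; a perfect fit (all ξ = 0) is reported as +inf. The
fitting loss is the reciprocal Σξ. When an evolved candidate network is
disconnected, its L is undefined and the objective scores it SI = 0, the
worst possible fit — parameters that disconnect the network are treated as
infeasible rather than erroring out of the search.

## Simulated annealing

The fit searches the lattice γ, η ∈ {0.2, …, 2.0} (10×10 by default, the
granularity at which results tables report exponents). Defaults: initial
temperature 1.0, geometric cooling 0.9 to a floor of 1e−3, 20 steps per
temperature, proposals of one lattice step along a uniformly chosen axis,
3 restarts. Worse moves are accepted with probability exp(−Δ(Σξ)/T); from
an infeasible state (loss = ∞) any move is accepted, so the walk can cross
disconnection plateaus instead of sticking. Every objective call at a
lattice point uses the same schedule-derived evolution seed, making the
objective a deterministic function of (γ, η); evaluations are cached, so a
full annealing run costs at most 100 distinct objective evaluations and an
exhaustive lattice sweep is a practical oracle (provided as
`exhaustive_search`).

## Synthetic data generator

The generator stands in for the imaging-derived inputs end to end.

- **Coordinates:** n points uniform in an ellipsoid with semi-axes
  70×85×60 mm, the rough extent of an adult cerebrum in MNI space.
- **Initial network:** a synthetic coupling matrix — distance decay
  exp(−d/40 mm) + 0.1 within spatially contiguous communities (seeded
  k-means of the centroids, 5 blocks) + a rank-one global factor with
  uniform(0,1) loadings (strength 1.0, producing hub cores) + Gaussian pair
  noise (sd 0.08) — thresholded at the density-matched cutoff (exactly
  round(density·n(n−1)/2) edges). If thresholding leaves multiple
  components, the weakest removable retained edge is swapped for the
  strongest component-bridging pair until connected, at constant edge
  count. An earlier design (spanning tree + distance-decaying attachment +
  triadic closure) was discarded because it cannot exceed C ≈ 0.3 at
  density 0.15, far below the C ≈ 0.6 typical of thresholded-correlation
  connectomes. The default parameters were calibrated once against the
  topological profile reported for a 90-node, density-0.15 resting-state
  group network (C ≈ 0.59, Eloc ≈ 0.77, M ≈ 0.27, L ≈ 2.0, Eglob ≈ 0.57,
  T ≈ 0.57); the generator attains C ≈ 0.58, Eloc ≈ 0.68, M ≈ 0.28,
  L ≈ 2.4, Eglob ≈ 0.50, T ≈ 0.54 on average. The residual gap (synthetic
  networks are slightly less integrated) is a known limitation.
- **Stage pairs:** the target is evolved from the initial network by the
  package's own MI model with known exponents (default γ = 0.2, η = 1.8)
  and quota α = 20, β = 40 — a net connection loss, matching the
  degeneration setting where later stages have fewer edges. The evolution
  seed is derived from the spec seed; seeds whose evolution disconnects the
  target are skipped so every forged target is a valid stage network. The
  generating parameters are returned as ground truth for recovery tests.
- **Time series:** Gaussian draws whose population correlation decays
  geometrically with graph distance (0.3 per hop), PSD-repaired by uniform
  diagonal inflation (which rescales correlations without reordering them)
  plus a noise variance term. At T = 500 samples, thresholding the sample
  correlation at the density-matched cutoff recovers ≥ 90% of the edges.

What passing tests on these synthetics do **not** show: the generator has
no hemodynamics, no global-signal artifacts, no measurement confounds, no
subject-level heterogeneity, and its community/hub structure is a
caricature of real cortical organization. Results on real data can differ
in ways the synthetic studies cannot reveal; the generator's role is to
validate the machinery (formulas, contracts, recoverability), not to
simulate biology.

## Study sizes used in the automated checks

The acceptance-style tests use 90-node, density-0.15 networks with 20
seeds for the deletion-trend study (β = 30, checkpoints every 10
deletions), 10 forged pairs for parameter recovery (quota 20/40, full
10×10 lattice, with exhaustive sweeps as oracles), and 10 seeds for the
MI-vs-random comparison on a reduced 3×3 lattice. These sizes were chosen
so the whole suite runs comfortably on a single CPU while keeping the
pass thresholds (≥ 80% trend steps, ≥ 8/10 exact recoveries, 10/10
orderings) statistically meaningful.

## Known limitations

- The min/max wording around SI in the source material is contradictory;
  the package treats larger SI as better, consistent with every reported
  result, and minimizes Σξ.
- The degree guard prevents isolated nodes but not global fragmentation;
  fragmenting parameter regions are scored SI = 0 rather than excluded a
  priori.
- Exact parameter recovery is only meaningful up to the ranking ties of the
  greedy evolution: distinct (γ, η) on the same ranking ray produce
  identical traces, and occasionally a neighboring lattice point achieves
  an equally perfect fit.
- Weighted, directed and dynamic-node-set graphs are out of scope.
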