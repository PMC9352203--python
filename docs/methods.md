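# Methods

This note documents the models and procedures `corrgraph` implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic fixtures do and do not establish about real
data.

## Correlation graphs

Rows of a `DataMatrix` are the entities to correlate (after an optional
transpose); columns are observations. Pearson correlation is computed by
centring and L2-normalising each row and taking dot products; Spearman is
Pearson on within-row average ranks (ties get the mean rank). Graph
construction proceeds in row tiles (default 512 rows) so that memory stays
quadratic in the tile, not in the number of rows, and sub-threshold entries
are never materialised.

Thresholding semantics: the default keeps an edge when r > r_min
(strict) and only for positive r, since a correlation graph built on
similarity usually has no use for anti-correlated neighbours; both choices
are exposed (`inclusive`, `polarity="absolute"`). Edge weights always keep
the signed r, so a downstream consumer can distinguish the two polarities
even under absolute thresholding.

Missing data are handled pairwise-complete: each pair of rows is correlated
over the columns where both are observed. Pairs with fewer than 3 shared
observations get no edge — two shared points always produce |r| = 1 and
would inject spurious edges. Rows with more than 50% missing cells are
dropped at load time with a warning, and rows with sample variance below
1e-12 (Pearson undefined) are removed by `drop_constant_rows` before graph
construction. No other normalisation is performed; log/quantile scaling is
deliberately left to the caller's preprocessing.

## Transform stack

All transforms are pure functions graph → graph and compose in declared
order. Choices worth noting:

* **k-NN pruning** uses the union rule — an edge survives when it ranks in
  the top-k weights of *either* endpoint. This guarantees every
  non-isolated node keeps its strongest edge (pruning can never create
  isolates) and makes the transform idempotent. Mutual (intersection) k-NN
  is available as a flag. Weight ties break by lexicographic edge id so the
  result is deterministic.
* **filter_nodes** evaluates its predicate against attribute values
  captured before any removal, so one application never cascades: removing
  a degree-1 node does not re-expose its neighbour to the same rule within
  that application. Degree-based outlier rules (e.g. "max incident r < 0.85
  and degree < 10") therefore behave order-independently.
* **contract_edges** takes the quotient over connected subgraphs of
  matching edges. The merged node keeps the lexicographically smallest
  member id, a `Members` text attribute (";"-joined ids) and a numeric
  `Member Count`. Parallel edges collapse to the maximum weight; numeric
  node attributes merge by taking the smallest-id member's value unless
  declared additive (then summed); self-loops vanish.
* Duplicate edges on import (including directed pairs folded to
  undirected) keep the maximum weight.

## Clustering

**Louvain.** Greedy multi-level modularity maximisation of
Q(γ) = Σ_c [e_c/m − γ(d_c/2m)²] with resolution γ as the single
granularity knob (γ = 1 is classical modularity; larger γ gives more,
smaller clusters). Local moves visit nodes in an order shuffled from the
seed and accept the neighbouring community with the largest gain, requiring
gain > 1e-9 so ties keep the current community; levels aggregate
communities into nodes (intra-community weight becomes a self-loop) until a
level yields no further gain. Runs are bit-reproducible for a fixed seed.
The internal per-level modularity trace is retained and is non-decreasing
by construction.

**MCL.** Markov clustering on the weighted adjacency with self-loops of
weight equal to each node's maximum incident weight (the standard damping
of odd-cycle parity effects). The column-stochastic flow matrix is
alternately squared (expansion) and raised entrywise to the inflation
exponent then column-renormalised (inflation), pruning entries below 1e-5,
until the matrix changes by less than 1e-8 or 100 iterations (then a
warning). Clusters are connected components of the limit matrix's nonzero
structure, which yields a hard partition directly. Negative edge weights
are replaced by their absolute values with a warning, as stochastic flow
requires non-negative similarities. Inflation is the granularity knob:
higher inflation never produces fewer clusters on planted fixtures.

A practical caveat measured during validation: on sparse planted blocks
(within-block edge probability ≈ 0.3 over 20 nodes) inflation 2.0 tends to
split blocks into two or three clusters — confirmed against an independent
dense-matrix implementation, so it is a property of the algorithm at that
density, not of this implementation. Inflation around 1.4–1.7 recovers
such blocks exactly; denser blocks (p ≥ 0.5) are recovered exactly at 2.0.
Granularity should be tuned to the sparsity of the graph at hand.

Cluster names are "Cluster 1..N" in descending size order (ties by smallest
member id). `aggregate_by_cluster` computes per-cluster mean profiles over
either matrix axis, the standard device for building a gene-level graph
from cell-level clusters.

## Metrics

* **PageRank**: power iteration with damping 0.85, uniform teleportation,
  edge weights as transition proportions, dangling (isolated) mass spread
  uniformly; converged when the L1 change drops below 1e-10 (error if 200
  iterations do not suffice). The result sums to 1.
* **Betweenness** (nodes and edges): Brandes' accumulation over unweighted
  (hop-count) shortest paths, per component, endpoints excluded, reported
  as raw pair counts without normalisation. Hop counts are used because
  correlation weights are similarities, not distances; treating them as
  path costs would invert their meaning.
* **Eccentricity**: max hop distance within the component; isolated nodes
  get 0. The edge value is the maximum of its endpoints' values — a display
  convention, since eccentricity is defined on nodes.

## Layout

Each component is laid out independently by a spring embedder: repulsion
k²/d between all pairs (k = ideal edge length = 1), computed through a
Barnes–Hut 2^d-tree with opening angle θ = 0.8; attraction w·d along edges,
giving an isolated pair a rest length of k/√w. A tenth of the net force is
applied per iteration, capped by a temperature that decays by 0.95 per
iteration to a floor of 0.005 (the floor keeps the layout able to escape
shallow local minima rather than freezing). Convergence is declared when
the mean applied displacement falls below tol·k (default tol 1e-3) or when
the mean net drift over a 25-iteration window falls below the same bound —
the latter catches stiff graphs that settle into a sub-pixel limit cycle.
Positions are initialised uniformly in the unit cube from a generator
derived from (seed, component rank), so layouts are bit-reproducible.

Components are then arranged concentrically: the largest at the origin,
the rest on rings of increasing radius in rank order, a ring closing when
the next component no longer fits its circumference. Ring radii and
angular gaps are chosen conservatively from component bounding radii (node
radius 0.5 included) so bounding spheres never overlap, with padding of at
least 10% of the larger radius. The layout is static (run to convergence);
`spring_step` is exposed for callers who want to drive the iteration
incrementally.

## Visual encoding

Categorical values are ordered by descending frequency (ties
lexicographic) and assigned colours from a fixed 20-colour
maximally-distinct palette, cycling with a logged warning beyond 20;
missing values get neutral grey (#bfbfbf). Numeric values map affinely:
t = (v − min)/(max − min), clamped, with t = 0.5 for a constant attribute;
colour interpolates linearly in sRGB along the ramp (white→red default) and
size is s_min + t(s_max − s_min) with defaults [0.5, 2.0]. Min/max scaling
(not percentile) was chosen for transparency; outlier-robust scaling can be
achieved by encoding a pre-transformed attribute.

## Synthetic fixtures

`planted_module_matrix` draws one standard-normal latent profile per module
and adds independent Gaussian noise with σ = √(1/ρ − 1), so the expected
within-module Pearson correlation is ρ while cross-module rows are
independent. `planted_partition_graph` is a stochastic block model with
separate weight ranges for within- (0.8–1.0) and cross-block (0.1–0.3)
edges. `dosage_matrix` emulates genotype data: integer dosages 0/1/2 from
binomial draws with population- and linkage-block-specific allele
frequencies. `toy_tree` builds regular rooted trees.

These generators reproduce the *shape* of real inputs (block correlation,
community structure, discrete dosages), not their marginal distributions:
no count overdispersion, dropout, library-size variation or linkage decay.
Passing tests on them demonstrates algorithmic correctness and contract
compliance, not biological recall on any particular dataset; thresholds and
granularities that work on fixtures still need tuning on real data.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
inputs — matrices of tens of rows, graphs of up to a few hundred nodes,
brute-force oracles on ≤ 12-node graphs, exhaustive modularity search on
6 nodes (Bell(6) = 203 partitions) — sizes at which the independent oracles
are exact and fast. The blocked correlation path and sparse MCL scale well
beyond that, but no large-scale benchmark is included.
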