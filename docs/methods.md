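# Methods

This note documents the models and conventions behind `netprio`: what
each stage computes, the defaults and why, what the synthetic generators
do and do not emulate, and the numerical decisions that make runs
bit-reproducible.

## Network model and input conventions

The pipeline operates on an undirected, unweighted simple graph over
gene symbols.  STRING-style exports carry a combined confidence score
per pair on a native 0–1000 integer scale; the configured threshold is
expressed on the 0–1 scale (default **0.4**, the conventional "medium
confidence" cutoff) and files with scores above 1 are rescaled before
comparison.  Cleaning is uniform across readers: symbols are upper-cased
(HGNC convention; prevents silent case mismatches when intersecting
lists), self-loops are dropped, duplicate pairs in either orientation
collapse to one edge, and nodes left with no passing edge are removed
(a `drop_isolated=False` flag retains them).  Confidence scores are not
used downstream: all fourteen indices are unweighted-topology
statistics, so the graph is treated as unweighted after filtering.

## The fourteen topological indices

All distance-based quantities use unweighted shortest paths and are
computed **per connected component**: pairs in different components are
excluded from sums rather than treated as infinitely distant, matching
the behavior of the standard Cytoscape analyzers.  Degenerate cases
(singleton components, degree < 2) return 0.  With $n_C$ the size of a
node's component, $d(v,w)$ the geodesic distance, $\sigma_{st}$ the
number of geodesics between $s$ and $t$ and $\sigma_{st}(v)$ those
passing through $v$ as an interior vertex:

- **Degree / NumberOfUndirectedEdges** — neighbor count.  On a simple
  graph the two coincide; both columns are kept because the downstream
  feature set is defined as fourteen named columns.
- **ClosenessCentrality** — $r / \sum_{w} d(v,w)$ over the $r$ reachable
  nodes.
- **AverageShortestPathLength** — $\sum_w d(v,w) / r$.
- **Radiality** — $\sum_w (\Delta_C + 1 - d(v,w)) / (n_C - 1)$ with
  $\Delta_C$ the component diameter.
- **Betweenness** (raw) — $\sum_{s<t} \sigma_{st}(v)/\sigma_{st}$;
  **BetweennessCentrality** is its normalized twin,
  $2\,\mathrm{Betweenness} / ((n_C-1)(n_C-2))$ for $n_C \ge 3$, else 0.
  The raw/normalized pair resolves the duplicated betweenness entry in
  the conventional fourteen-column export.
- **Stress** — $\sum_{s<t} \sigma_{st}(v)$, the geodesic count itself.
- **ClusteringCoefficient** — $2 e_N / (k(k-1))$, edges among neighbors.
- **NeighborhoodConnectivity** — mean degree of the neighbors.
- **TopologicalCoefficient** — mean over partner nodes $w$ (nodes
  sharing at least one neighbor with $v$) of $J(v,w)/k_v$, where
  $J(v,w)$ counts shared neighbors plus 1 if $v$ and $w$ are adjacent
  (the "+1 if adjacent" variant used by NetworkAnalyzer).
- **MNC** — size of the largest connected component of the subgraph
  induced by $v$'s neighbors ($v$ excluded).
- **Bottleneck** — the number of roots $s \ne v$ whose shortest-path
  tree hangs more than $n_C/4$ nodes below $v$.  BFS trees are not
  unique; equal-distance parent choices are broken by lexicographically
  smallest parent symbol so that the statistic is deterministic.
- **EPC** — Monte-Carlo mean, over random subgraphs in which each edge
  is independently retained with probability $p$, of the size of $v$'s
  component.  Defaults: $p = 0.5$, 1000 iterations, seeded; the defaults
  are package choices (the index has no canonical parameterization) and
  both are exposed in config.  At $p = 1$ the estimate equals the
  component size exactly; at $p = 0$ it is 1.

Production code computes all-pairs distances and geodesic counts with
per-source BFS, then obtains betweenness and stress from the identity
"$v$ lies on an $s$–$t$ geodesic iff $d(s,v) + d(v,t) = d(s,t)$, in
$\sigma_{sv}\sigma_{vt}$ ways".  The test suite checks every
deterministic index against explicit all-geodesic enumeration (and
betweenness additionally against an independent Brandes implementation)
on hundreds of random graphs, to within $10^{-9}$.

**Hub intersection.**  Hub candidates are genes in the top-$k$ of MNC,
EPC, Bottleneck and Betweenness simultaneously.  Top-$k$ selection is a
*closed ranking*: every gene tied with the $k$-th largest value is
included, which makes the result independent of symbol order and nested
as $k$ grows.  $k$ has no canonical value and must be set explicitly in
config; the result is returned ordered by mean rank across the four
metrics.

## Prioritization workflow

**Cleaning.**  Rows whose missing fraction is ≥ `sample_missing_max` are
removed first; remaining columns with missing fraction below
`feature_missing_max` are mean-imputed.  Both default to 0.5%.  Note the
literal consequence: in a 14-column table a single missing value is
7.1% of a row, so any incomplete gene is removed and column imputation
only engages at laxer, user-set thresholds.  The rule is applied as
stated and the thresholds are exposed.

**Standardization.**  Per-column z-scores with population SD; constant
columns map to zero rather than NaN.

**K-means and the elbow.**  Lloyd's algorithm with seeded greedy
k-means++ initialization, Euclidean distance, `max_iter=300`,
`tol=1e-4` (squared Frobenius norm of the centroid shift).  A single
seeded initialization is the default so that runs are reproducible
across library ecosystems; `n_init` is configurable.  The cluster count
is chosen over $k = 1..10$ as the interior maximizer of the WCSS second
difference $W(k{-}1) - 2W(k) + W(k{+}1)$, ties resolving to the smaller
$k$.  When the maximal second difference is below 5% of the WCSS at the
smallest $k$, the curve has no real kink and the result carries a
`weak_elbow` flag plus a warning — degenerate elbows are made visible
instead of silently returning an argmax.

**Isolation Forest.**  100 trees grown on seeded subsamples of
$\lceil 0.8 n \rceil$ rows; at each node a random feature with positive
range and a uniform split inside the observed range; height limit
$\lceil \log_2 m \rceil$.  The anomaly score is
$s(x) = 2^{-\bar h(x)/c(m)}$ with $c(m) = 2H(m-1) - 2(m-1)/m$ the mean
unsuccessful-search depth of a binary search tree (harmonic numbers are
computed exactly for small $m$).  Flagging is by score quantile: the
$\lceil \mathrm{contamination} \cdot n \rceil$ highest scores are
flagged, ties at the cutoff all included — this yields a reproducible
flag count, unlike offset-based thresholds.  Contamination defaults to
0.10 and must lie in (0, 0.5].  When all rows are identical every score
equals $1/2$ and the tie rule flags all rows.

**PCA.**  Column-centered SVD; the first two components are reported
with explained-variance fractions.  Each component's sign is fixed so
its largest-magnitude loading is positive, removing the SVD sign
ambiguity.

**Composite score.**  Eleven indices rank descending (larger = more
important); three rank ascending: AverageShortestPathLength,
TopologicalCoefficient and ClusteringCoefficient — short paths, low
shared-neighbor normalization and low local clustering are the hub-like
signatures.  The third ascending member is fixed by elimination from
the fourteen-name list and the whole direction map is overridable in
config.  Ranks are fractional (mean of tied positions): deterministic,
order-independent, and rank-sum conserving, so the mean composite score
over genes is exactly $(n+1)/2$ and the score is invariant under any
strictly monotone transform of a single index.  Genes are re-ranked by
ascending composite score; the core-gene rule selects Isolation-Forest
outliers with composite rank ≤ 20 (threshold configurable).

In the full pipeline the prioritization stage runs on the
hub-intersection subset by default (`ml_on_hub_subset`), mirroring the
two-stage funnel the workflow is designed around; a flag runs it on all
genes instead.

## Synthetic data: what is emulated, what is not

`generate_ppi` grows a connected preferential-attachment graph (first
two nodes joined, each later node attaching to `edges_per_new_node`
degree-weighted targets) and plants `n_hubs` super-hub genes drawn from
the later three quarters of the growth order.  Hub $j$ receives
$(j+1) \cdot \texttt{hub\_extra\_degree}$ extra neighbors chosen
degree-weighted without replacement, then is topped up with random
attachments until it strictly exceeds the highest filler degree.  Three
properties motivate this construction: degree-weighted partners give
hubs the connected neighborhoods that MNC rewards (uniformly chosen
partners produce star-like hubs with nearly edgeless neighborhoods,
which real interactome hubs do not have); the staggered boosts mirror
the spread-out degrees of real apex genes and make each planted hub
individually extreme in feature space rather than one of five clones;
and the top-up makes "planted hubs dominate the degree ranking" a
construction guarantee, so recovery tests measure the pipeline, not the
generator's luck.  What is *not* emulated: STRING score distributions,
community structure, biological annotation; degree heterogeneity is the
only claim, because that is what the composite score exploits.  Passing
recovery tests therefore show that the pipeline surfaces dominant hubs
under scale-free-like degree heterogeneity — not that it recovers
biology from real networks.

`generate_target_sets` produces two lists with exact cardinalities
$(K, M)$ and an exact intersection $x$ from a universe of $N$ filler
symbols.  `generate_feature_clouds` places unit-variance Gaussian
clusters on the vertices of a randomly rotated regular simplex with
side `separation` (exact whenever $\text{clusters} - 1 \le \dim$ —
equidistance matters, because an irregular layout inflates WCSS(1) and
biases the raw second-difference elbow toward $k = 2$), and appends
outlier rows at `outlier_distance` SDs from the centroid mean.
`generate_gmt` plants enriched sets drawing 80% of members from a query
list.  Planted entities are named `HUB1…`/`PLANTED_SET_…`, fillers
`G000001…`, so ground truth is grep-able.  Every generator is a pure
function of (parameters, seed).

Default experiment sizes — 364-node networks with 5 planted hubs, 50
recovery replicates, 100 elbow seeds on 3 clusters × 50 points at
separation 10, 20 Isolation-Forest seeds on 120 cluster points plus 12
planted outliers at distance 10 — are the package's reference study
conditions and are what `scripts/acceptance.py` reruns.

## Overlap and enrichment statistics

The overlap test is one-sided (upper tail) — the scientific question is
over-representation, and excess depletion is not of interest.  The tail
$\sum_{j \ge x} \binom{M}{j}\binom{N-M}{K-j}/\binom{N}{K}$ is evaluated
as a log-sum-exp over log-gamma binomial coefficients, stable for
genome-scale $N$ and for tails far below the double-precision underflow
threshold; results are stored on the log scale.  The universe size $N$
is a required explicit argument — defaulting it silently is the main
way overlap tests get misused.  Correctness is pinned two ways in the
tests: exact agreement (to $10^{-9}$ relative) with a big-rational
`Fraction` oracle over the full $N \le 30$ parameter grid, and
3-significant-digit log10 agreement at $(N, K, M, x) =
(19871, 742, 5583, 364)$, where the exact tail is $10^{-34.21}$ — a
useful reminder that quoted bounds of the form $p < 10^{-50}$ can be
orders of magnitude below the value the stated inputs actually imply;
the package reports the computed value alongside any claimed bound.

ORA restricts each gene set to the declared universe, applies the same
tail test, and adjusts across sets with Benjamini–Hochberg step-up
(capped at 1, monotone, original order restored).  Query genes outside
the universe are dropped with a warning.  Under a null of uniformly
drawn queries the p-values are super-uniform (empirical type-I at
$\alpha = 0.05$ stays ≤ 0.07 in the test suite's 2000-replicate check).

## Reproducibility

Every stochastic operation takes an explicit seed (default 42).  The
pipeline derives per-stage substreams as
$(\mathrm{seed} \cdot 1000003 + \mathrm{crc32}(\mathrm{stage})) \bmod 2^{31}$,
so stages are individually reproducible and independent.  Output CSVs
are written with deterministic row order (composite rank, then gene);
the manifest records config, input SHA-256 hashes, per-stage
cardinalities and the package version.  Two runs with equal config and
inputs produce byte-identical tables and manifests equal up to
timestamps.

## Known limitations

- Centralities are exact but not asymptotically optimal
  ($O(n \cdot E)$ BFS plus an $O(n^3)$ vectorized pair scan for
  betweenness/stress); comfortable to a few thousand nodes, not for
  proteome-scale graphs.
- The Isolation Forest flags by count, so the flagged fraction is
  $\lceil cn \rceil / n$, slightly above $c$ at small $n$.
- The elbow rule inherits the known brittleness of raw second
  differences on smooth WCSS curves; the weak-elbow flag surfaces, but
  does not repair, such cases.
- Identifier handling is string-level (upper-cased symbols); no
  synonym or cross-database mapping is attempted.
- The synthetic generators validate mechanics, not biology (see above).
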