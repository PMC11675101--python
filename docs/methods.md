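# Methods

## Scope and data model

`pmnet` analyzes weighted-undirected brain graphs built from
probabilistic tractography between 23 posterior-parietal and 14
premotor ROIs per hemisphere (37 nodes).  A subject's raw input is a
directed count matrix (row = seed) plus a positive waytotal per seed;
normalization divides each row by its waytotal, and directional
averaging symmetrizes the matrix.  Entries exceeding the waytotal are
surfaced as warnings rather than silently clipped — they indicate a
data problem upstream.

Two graph scopes coexist deliberately.  The *full* 37-node graph,
including intralobar (parietal–parietal, premotor–premotor) edges,
carries the admission criteria and the node-role metrics: clustering —
and therefore small-worldness — is identically zero on a bipartite
graph, so screening a parieto-premotor-only graph for small-world
topology would be vacuous.  The *interlobar* graph (322
parietal×premotor pairs; intralobar pairs are absent edges, not
zero-weight edges) carries the edge-level analyses: distance ranking,
lateralization tests and variability clustering.  The interlobar mask
is idempotent and its retained-pair count is always
n_parietal × n_premotor.

## Group aggregation and admission

The default group consensus is the edgewise mean across subjects.  The
variant `mean_plus_2sd` (mean + 2 × sample SD, divisor n−1) is provided
because the literal "mean(P_ij) + 2 SD(P_ij)" expression admits both a
group-weight and an inclusion-cutoff reading; the package implements
both and asserts neither as canonical.  Sample SD (ddof = 1) is used
everywhere an SD over subjects appears, since subjects are a sample.

Thresholding retains edges with weight ≥ t (weak sub-threshold edges
are removed; the boundary is inclusive and documented).  The default
sweep 0.01–0.1 in 0.0025 steps gives 37 graphs.  Each graph is
admitted iff it is connected (isolated nodes fail connectedness rather
than being dropped), its maximized Newman modularity exceeds 0.3, and
its small-worldness quotient exceeds 1.

C and L for admission are the binary Watts–Strogatz forms
(C_i = 2t_i/k_i(k_i−1), hop-count path lengths) on the binarized
adjacency, matching the admission criteria's definitions; weighted
variants of the node metrics are the default elsewhere.  The null
model is Maslov–Sneppen degree-preserving rewiring with 10×edge-count
swap attempts; rewirings that disconnect the graph are redrawn (bounded
retries) because L is undefined on disconnected graphs, and graphs
admitting no swap (complete graphs) are returned unchanged, making
S = 1 exactly there.  n_null defaults to 100 and all randomness derives
from a user seed via `numpy.random.SeedSequence`.

## Modularity maximization

Weighted Newman modularity
Q = (1/2W) Σ_ij (w_ij − s_i s_j/2W) δ(m_i, m_j) is maximized by
recursive spectral bisection on the (generalized) modularity matrix
with a Kernighan–Lin sweep after each split, followed by a refinement
loop that alternates greedy single-node moves, a multi-module KL pass
(nodes moved at a loss with the best intermediate partition kept),
joint pair moves/exchanges, module merges, and in-place spectral
re-splits, from three deterministic starts (the spectral tree, all
singletons, one module).  Tie-breaks are by lowest node index, so
results are deterministic for a fixed input.  Q of the one-module
partition is exactly 0 by construction.

The refinement is still a local search: on near-uniform random graphs
whose optimal Q is itself small (≲ 0.1, i.e. graphs with essentially no
modular structure) it can return a partition a few 1e-3 below the
global optimum found by exhaustive enumeration.  On modular graphs —
including every admission-range graph exercised in the tests — it
matches brute-force enumeration exactly.

## Distances and node roles

Weights convert to lengths by the reciprocal transform (the standard
choice; higher weight ⇔ strictly shorter length), and all-pairs
distances come from Dijkstra's algorithm via `scipy.sparse.csgraph`.
Percentile classes (strictly below the 15/25/50/75th percentile,
linear interpolation) are computed over the finite parieto-premotor
distances of one hemisphere only; unreachable pairs are excluded from
the percentile population and classed `none`.  The analysis graph is
the admitted graph of maximal edge density, ties resolved toward the
lowest threshold.

Participation coefficient and within-module degree z-score default to
their weighted (strength-based) forms to match the weighted graph; a
binary option is retained.  Module affiliations come from each
threshold's own modularity run, not a consensus partition.  Stage 1
requires the Q3 criterion at both the lowest and the highest admitted
threshold — the reading that excludes nodes passing only at occasional
thresholds — and needs ≥ 2 admitted thresholds.  A node meeting both
connector and provincial criteria is assigned connector and flagged as
dually qualified.  Stage 2 quartiles (strength, betweenness; strict
">" up-arrow, "≤" down-arrow) are computed on the analysis graph over
all nodes.  Betweenness is Brandes' algorithm on the connection-length
matrix, normalized by (n−1)(n−2) over ordered endpoint pairs.

Peripheral nodes are nonhubs with strength *and* betweenness strictly
below the first quartile.  On sparse weighted graphs this rule can be
structurally unsatisfiable: when more than a quarter of nodes have
betweenness exactly 0 (shortest paths concentrate on a few bridge
nodes), Q1(betweenness) is 0 and nothing lies strictly below it.  The
default synthetic cohort is in this regime, so its planted
low-strength nodes are recovered as low-strength nonhubs but not
labeled peripheral; on dense empirical networks with continuous
positive betweenness the rule behaves as intended.

## Edge statistics

Paired two-sided t tests run per interlobar connection across subjects,
with absent connections entering as weight 0 (a zero count is an
observation, not missing data).  Degenerate edges: all-zero differences
give t = 0, p = 1; constant nonzero differences give the smallest
representable p with a degeneracy flag, so synthetic extremes cannot
crash the pipeline.  BH-FDR adjustment uses `statsmodels`
(`fdr_bh`); significance is adjusted p ≤ α = 0.05.  The coefficient of
variation (sample SD / mean; undefined and flagged at mean 0) is
clustered by hemisphere-wise quartiles: A < Q1 ≤ B < Q2 ≤ C < Q3 ≤ D.
The CV, not the SD, is the clustered quantity — the source description
mentions both, and the operative definition is quartiles "of CV values".

## Synthetic cohorts

The generator emulates the study conditions: 40 subjects, two
hemispheres, 37 ROIs, waytotal 100 000 streamlines per seed (5 000 per
voxel across a few dozen voxels is this order of magnitude).  Expected
normalized weights are block-structured over four planted modules that
each span both lobes, 0.05 within and 0.005 between modules (10:1).
Planted connector hubs (hIP3, PM6d1) triple their cross-module edges,
provincial hubs (Area45, 5L) their within-module edges; planted
low-connectivity nodes (PFop, 7M) scale all incident edges by 0.4; ten
interlobar edges carry a left/right expectation ratio δ = 2.

Counts are Poisson(waytotal × weight × noise) independently per
direction, with a mean-one lognormal subject×connection noise factor
(σ = 0.2) drawn independently per hemisphere, and counts capped at the
waytotal (a seed cannot emit more streamlines than its budget).  A
fixed mean-one lognormal per-pair anatomical factor (σ = 0.5, seeded,
shared between hemispheres) makes edge weights heterogeneous the way
real streamline counts are; without it every shortest path is a direct
edge and betweenness degenerates to zero on all non-bridge nodes.  A
deterministic mode replaces Poisson draws by the rounded expectation
for exact-recovery tests.  Cohorts are bit-reproducible from the spec
seed.

What passing tests on these cohorts shows — and does not.  The
generator produces the planted block/hub/asymmetry structure with
realistic count noise, but not spatial autocorrelation between
neighboring ROIs, distance-dependent false positives of tractography,
gyral-bias effects, or heavy-tailed subject outliers.  Recovery of
planted structure therefore validates the pipeline's statistical
machinery, not tractography itself.

## Problem sizes and numerical choices

The test suite runs the full pipeline on 40-subject cohorts with
n_null = 10 nulls per graph for speed (the acceptance computations use
the default 100); type-I calibration uses 50 cohorts × 322 edges;
hub-recovery uses 20 cohorts.  Quartiles and percentiles use numpy's
linear interpolation throughout.  Threshold grids are generated by
integer stepping and rounded to 12 decimals so 0.01 + k·0.0025 counts
are exact.  All RNG flows through `numpy.random.SeedSequence` children,
so per-threshold null draws are independent and reproducible.
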