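# Methods

## Graph model

A pathway is a simple directed graph over gene-encoded elements. The
adjacency matrix is strictly binary: parallel edges collapse, and
self-loops are removed at construction (logged with a count). None of the
centrality recurrences treat self-influence, and KGML occasionally encodes
autoregulation, so removal keeps the adjacency consistent with the
neighbourhood definitions; this is a package policy, not something the
upstream formulations prescribe. The undirected projection is represented
as a symmetric directed graph (each arc plus its reverse), so every
centrality has a single code path. Node order is fixed at construction and
shared by transposition and symmetrization, which makes elementwise
identities (source-of-transpose = sink, SSC = source + sink) exact.

## Centrality models

All spectral variants are fixed points of `C = β + M C` with a
non-negative contraction `M`; the closed form `C = (I − M)⁻¹ β` equals the
Neumann series `Σ Mᵏ β` whenever the spectral radius of `M` is below 1.
Degree matrices are clamped at 1 (`max(deg, 1)`) inside the PageRank and
Laplacian operators only — degree centrality itself reports unclamped
degrees.

Defaults: PageRank α = 0.85, β = 0.15 (the classic damping/restart
values); Katz α = 0.1, β = 1, small enough to admit graphs with spectral
radius up to 10 (the filter bound below); Laplacian α = 0.85, β = 1 for
consistency with PageRank. Both SSC components always use the same (α, β).
All are configurable per run.

Two deliberate deviations from textbook conventions:

* PageRank is the literal solve with a constant restart vector — no
  dangling-node mass redistribution, no sum-to-one renormalisation. Raw
  scores therefore differ from stochastic-matrix PageRank implementations,
  though rankings on a fixed graph are closely related; the validation
  pipeline works on within-pathway ranks and z-scores, which are invariant
  to any global affine rescaling.
* Katz is refused at `α ≥ 0.999/λ₁` rather than exactly `1/λ₁`: just past
  the radius the inverse may still exist numerically while the series
  diverges, so a small safety margin keeps "computable" aligned with
  "meaningful".

Closeness uses the harmonic convention (sum of reciprocal distances,
unreachable pairs contribute 0, `d(v,v)` excluded), which is the only form
that stays finite on the weakly connected, frequently acyclic graphs
pathways produce.

Solvers: dense LU solve by default; an iterative fixed-point solver
(initialised at β, max-norm tolerance 1e-12, 10 000-iteration cap) is
provided and agrees with the closed form to 1e-9 under the contraction
condition. Spectral radii use dense eigendecomposition up to 200 nodes and
shift-by-identity Arnoldi iteration (deterministic start vector) above,
with a dense fallback when the spectral gap is too small for Arnoldi.

## Pathway quality filters

Applied in a fixed order, first failing rule reported: (1) more than 1000
nodes **and** more than 4000 edges; (2) at most 20 nodes **or** at most 20
edges; (3) adjacency spectral radius above 10 (which would force a tiny
Katz α); (4) any configured centrality constant across nodes (no ranking
information); (5) five or fewer important genes (unstable p-values). The
AND/OR asymmetry of rules 1–2 is intentional and implemented literally.
Gene matching between graphs and gene sets is exact string match; no
identifier-mapping service is bundled.

## Validation pipeline

**Quantile ranking.** Within a pathway, nodes are ranked ascending by
score and mapped by `Q = ⌈100·rank/n⌉`, so the top node is always in
quantile 100 and the bracket can never produce a 0 bin. Ties take the
average rank before the ceiling — deterministic, order-independent, and
consistent with the Wilcoxon tie convention. Pooled counts treat each
(gene, pathway) occurrence as a separate observation; empty bins are
omitted from the regression, which requires at least 3 populated bins.

**Regression.** Ordinary least squares of the per-quantile importance
percentage on the quantile index, via statsmodels; slope, intercept,
standard errors, two-sided t p-values and adjusted r² are reported.

**CDF comparison.** Scores are z-normalized per pathway with the sample
(n−1) standard deviation — the estimator convention is configurable and
immaterial to ranks — then pooled across pathways and quantiled by pooled
rank (a distinct discretization from the within-pathway quantiles, kept as
a separate code path). The one-sided two-sample KS statistic is
`D = sup (F_other − F_important)`, clamped at 0; its p-value is the
one-sided Smirnov asymptotic with Hodges' second-order correction, which
matches scipy's asymptotic one-sided implementation to machine precision.

**Per-pathway tests.** Welch's t (implemented from the definition, with
Welch–Satterthwaite degrees of freedom, one-sided: important > other) and
the Wilcoxon rank-sum test (exact null below combined n = 50 without ties,
otherwise normal approximation with tie and continuity correction, via
scipy). Groups smaller than 2 (Welch) or empty (Wilcoxon) are marked
untestable and leave their FDR family. Benjamini–Hochberg runs per
(model, variant, test) family; a result is flagged at adjusted p strictly
below the level (default 0.05).

**Sensitivity scan.** The four PageRank variants are recomputed on a grid
of α values (default 0.10–0.90, step 0.01, 81 points) and refitted; the
SSC and undirected fits are compared at each α by Fisher's
Z-transformation of the two fit correlations,
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.

## Synthetic cohorts

The generator emulates the canonical shape of a signaling pathway: a
narrow first layer (receptor-like, dense fan-out), wider sparsely wired
middle layers, and a narrow last layer (effector-like, dense fan-in).
Defaults: 150 pathways, 5 layers, middle layers of 6–12 nodes, terminal
layers half that width (minimum 3), adjacent-layer edge probability 0.22
(0.75 at terminal layers), forward skip probability 0.03, 10% of nodes
degree-boosted hubs, importance rate 0.5 at the planted locations with a
4× diluted background. These widths and densities give pathways of ~30–45
nodes and ~60–100 edges — comfortably inside the quality filters — and an
overall important-gene fraction around 20–25%, similar to cancer-gene
annotation density in disease pathways. Graphs are DAGs (spectral radius
0, so Katz is valid at any α) unless a feedback probability is set to
exercise the cyclic solvers. Every pathway derives its own seed as
`seed + index`, so cohorts are reproducible and stable under extension.

Under `terminal_ends` planting, the bottleneck-and-fan geometry gives
first-layer nodes high source centrality and last-layer nodes high sink
centrality, so their sum ranks both ends above the sparse middle for
Katz, PageRank, degree and closeness — while each pure component places
one planted end at the very bottom of its ranking, yielding the
U-shaped (net-flat) quantile profile that motivates summing the
components in the first place.

One deliberate limitation: the degree-averaged (Laplacian) model is
insensitive to degree by construction, and on a purely layered geometry
its source value is a concave increasing function of the remaining
downstream depth. The sum of that function evaluated from both ends peaks
mid-pathway, so on these synthetic cohorts Laplacian-SSC ranks middle
nodes above terminal ones and its regression slope is *negative* under
terminal-ends planting. Real curated pathways are not pure layered chains
— hubs, dead-end branches and unequal cascade lengths give the Laplacian
model signal the generator deliberately lacks. Passing tests on these
cohorts therefore demonstrate signal recovery for the degree-sensitive
models and calibration of the statistics; they do not certify
Laplacian-SSC behaviour on real data, and `expected_signal` only states
contracts the construction actually warrants.

Under `uniform` planting there is no topological signal; the pipeline's
slope test is calibrated (empirically slightly conservative, since the
per-bin fractions are bounded percentages rather than Gaussian), and BH
at 5% almost always yields zero significant pathways.

## Problem sizes

The test suite validates dualities on 200 random graphs (up to 50 nodes),
solver-oracle agreement on 100 contraction graphs, statistical components
against independent references (scipy, statsmodels, closed forms and full
enumeration of rank assignments) on 1000 random fixtures each, signal
recovery on 100 replicate cohorts of 150 pathways, and type-I control on
200 replicate null cohorts of 30 pathways. These sizes keep the full suite
around a minute on one CPU while leaving the binomial margins of the
replicate counts wide.

## Known limitations

* Edge weights, activation/inhibition signs and multigraphs are out of
  scope; the adjacency is strictly binary.
* KGML multi-gene entries and groups are fanned out to one node per gene
  identifier; other expansion conventions exist and yield different node
  counts on the same file.
* Weighted source/sink combinations (anything other than the equal-weight
  sum) are not implemented.
* Betweenness has no meaningful source/sink split (shortest paths are
  preserved under transposition) and is deliberately absent.
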