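# Methods

This note documents the models implemented in netbackbone, their
assumptions, the numerical choices behind them, and what the synthetic
generators do and do not emulate.

## Graph model and detection heuristic

Undirected weighted graphs are stored as dense symmetric adjacency
matrices with a zero diagonal and ordered string labels; bipartite
networks as binary agents × artifacts incidence matrices.  Weights
must be finite and nonnegative; NaN/Inf are rejected at read time.
Undirected edges are emitted once, endpoint labels in sorted order, so
the edgelist writer is canonical and round-trips byte-identically.

`suggest_model` classifies a matrix by value, not container: binary
and rectangular (or square non-symmetric) → bipartite incidence
(suggest SDSM); non-binary → weighted unipartite (suggest disparity);
binary symmetric square → unweighted unipartite (suggest L-Spar).  A
*projection warning* is raised for square symmetric nonnegative-integer
matrices with an off-diagonal entry above 1 — the signature of a
co-occurrence count matrix, for which the weighted-network models are a
poor fit because they ignore the underlying incidence structure.  This
rule is a documented approximation: it covers the printed behaviors of
the heuristic it emulates, which also inspects language-specific object
classes that have no equivalent here.

## Weighted models

**Global threshold.**  Keep edge (i, j) iff w_ij > t (strict).  When t
is given as a statistic ("mean", "median", quantile, or a callable) it
is evaluated over *all* cells of the full adjacency matrix, zeros and
diagonal included.  This matters: on the 10-node toy matrix the
all-cells mean is 11.62 while the mean over the 21 edges alone is
27.7, and the two thresholds select different backbones.  The
convention matches applying the statistic to the matrix object itself,
which is how the threshold is specified in the workflow this package
follows; both conventions coincide in the edge sets they select on the
toy network.

**Disparity filter.**  Null: node i's strength s_i is split uniformly
at random among its k_i edges (k_i − 1 uniform break points), so the
normalized weight p = w_ij/s_i of one edge has upper tail
(1 − p)^(k_i − 1).  The edge-level upper-tail p-value is the minimum
over the two endpoint values — an edge is retained when significant
from *either* endpoint, the published rule for this filter.  Degree-1
endpoints contribute a value of 1 (the 0^0 ambiguity never arises and
the edge can still be kept through its other endpoint).  The null is
continuous, so p_lower = 1 − p_upper.  P-values are invariant under
uniform rescaling of all weights.

## Bipartite models

All bipartite models test the projection weight P_ij = Σ_k B_ik B_jk
against the distribution of the same quantity in random incidence
matrices; they differ in what they constrain.  Every dyad is tested
(not only those with P_ij > 0), so signed extraction can flag
significantly *weak* pairs whose observed overlap is zero.

**SDSM.**  Row and column sums are constrained on average.  Cell
probabilities come from the maximum-entropy bipartite configuration
model: Q_ik = x_i y_k / (1 + x_i y_k) with fitness parameters solved by
damped fixed-point iteration (damping 0.5, tolerance 1e-8 on the worst
margin residual, at most 10⁴ iterations; non-convergence raises an
error naming the worst margin).  Empty or saturated rows/columns are
peeled off first and assigned Q = 0 or 1, with the remaining margins
adjusted, so degenerate inputs (all-ones, all-zeros) are exact.  This
maximum-entropy estimator was chosen over regression-based historical
estimators because it is deterministic, dependency-free, and
reproduces the margins to solver precision; the choice is recorded in
the result metadata.  Given Q, the null weight of dyad (i, j) is
Poisson-binomial with parameters {Q_ik Q_jk}_k, computed exactly.

**Poisson-binomial kernel.**  Exact PMF by sequential convolution
(dynamic programming, O(n²)) up to 1024 components; beyond that, a
refined normal approximation with continuity and skewness correction
(Φ(z) + γ(1 − z²)φ(z)/6).  The crossover is configurable.  Boundary
tails (w = 0, w = n) are returned as exactly 1.

**FDSM.**  Row and column sums fixed exactly; the margin class is
sampled by the curveball algorithm (two random rows swap a shuffled
subset of their non-shared artifacts — a trade — which preserves both
margins and whose chain converges to the uniform distribution on the
class).  Samples are taken sequentially, 5r trades apart (r = number
of agents), with no separate burn-in beyond the first 5r trades.
Empirical p-values use the add-one estimator (1 + hits)/(trials + 1),
which is never exactly 0 and therefore safe to feed into multiple-test
corrections; it is biased by at most 1/(trials + 1), negligible at the
trial counts used.  When `trials` is omitted, the count is the
smallest n at which the 95% binomial confidence interval for a
p-value near α has half-width ≤ α/10, i.e. n = ⌈1.96² · 100(1 − α)/α⌉
(7,300 at α = 0.05).  This documented rule is this package's own
calibration; other implementations choose trial counts differently.

**fixedrow / fixedcol / fixedfill.**  Closed-form nulls constraining
only row sums (hypergeometric: W ~ Hyp(c, d_i, d_j)), only column sums
(Poisson-binomial over artifacts with π_k = (f_k/r)·((f_k−1)/(r−1)),
identical for all dyads, so its CDF is computed once), or only the
fill q = ΣB/(rc) (W ~ Binomial(c, q²)).

For discrete nulls P(W ≥ w) + P(W ≤ w) = 1 + P(W = w), so the two
tails overlap by the point mass; extraction uses strict inequality
p < α throughout.

## Inference

The family for multiple-test correction is the set of tested dyads:
positive-weight edges for weighted models, all dyads for bipartite
models.  Corrections (bonferroni, holm, BH, BY) are applied via
standard step-down/step-up formulas.  Signed extraction is two-tailed
at α/2 per tail, with the two tails corrected separately over the same
family — the correction interacts with tail choice, and separate
adjustment keeps the signed backbone equal to the union of the two
one-tailed extractions at α/2.  The familywise error rate over m
independent tests is 1 − (1 − α)^m.

Narrative output reports edge reduction 100·(1 − E_b/E_0) over
undirected positive-weight edges and connected-node reduction over
nodes of degree ≥ 1, rounded to one decimal with a trailing ".0"
trimmed (so 40.0 prints as "40%", 76.19 as "76.2%").

## Sparsification

Pipeline: score → normalize → filter → connect.

- *Scores*: Jaccard |N(i)∩N(j)|/|N(i)∪N(j)| with open neighborhoods
  (a node's neighborhood excludes itself but includes the other
  endpoint; the convention is fixture-tested: each triangle edge
  scores 1/3); triangle count; neighbor degree (directional: the score
  of (i, j) from i's side is deg(j)); or seeded iid uniform.
- *Normalize*: competition ranking per node, descending score, ties
  sharing the best (minimum) rank — deterministic, no random
  tie-breaking.
- *Filter*: per-node budget ⌈d^s⌉ on ranks with union semantics (an
  edge survives if either endpoint keeps it), a threshold, or a global
  proportion.  The ceiling and the union rule make the filter
  monotone in s and guarantee every connected node keeps at least its
  rank-1 edge, so connected-node reduction is 0% by construction.
- *Connect* (optional): union of maximum-score spanning trees, one per
  component, computed by descending Kruskal with tie-group analysis
  (an edge is in some maximum tree iff it joins two components of the
  forest of strictly higher-scoring edges).  Spanning trees are taken
  as *maximum* on similarity scores — equivalent to minimum spanning
  trees on the distance transform 1/score — because all scores here
  are similarities.

Presets: L-Spar = (jaccard, rank, degree filter); Local Degree =
(degree, rank, degree filter).  Quadrangle-completion scores are not
implemented in this version; the triangle score is the nearest
available analogue.

## Synthetic generators

- `toy_weighted()` — a fixed 10-node, 21-edge matrix: two hub-and-spoke
  clusters at different weight scales (spokes 10 vs 100) joined by a
  weight-75 bridge.  Exercises exactly the failure mode of global
  thresholds on multi-scale networks.
- `bipartite_blocks()` — 3 aligned groups of 10 agents × 25 artifacts;
  cell probability 0.8 within group, 0.2 between.  The projection is
  complete or nearly so, hiding the groups; bipartite nulls recover
  them.
- `sbm()` — 60 nodes, three 20-node communities, edge probabilities
  0.75 within / 0.25 between.
- `preferential_attachment()` — 60 nodes, 3 attachments per new node,
  grown from a connected 4-clique seed (so the graph is connected with
  exactly nm − m(m+1)/2 = 174 edges).

All are pure functions of parameters and seed (NumPy Generator
streams).  They emulate planted structure and degree heterogeneity but
not features of real data such as weight heavy-tails beyond two
scales, degree–strength correlations, or missing data; passing tests
demonstrate correctness of the machinery on known ground truth, not
performance guarantees on empirical networks.

## Problem sizes and tolerances

Oracle tests compare: the Poisson-binomial DP against full 2^n
enumeration (n ≤ 12, tolerance 1e-12); the BICM against an independent
nonlinear root solve of the margin equations (atol 1e-6) and against
its own margin constraints (1e-6 on random 20×30 incidences); SDSM
p-values against 50,000 Bernoulli(Q) Monte-Carlo draws (3 standard
errors) on a 6×8 planted fixture; FDSM against exhaustive enumeration
of 3×3 and 3×4 margin classes (20,000 trials, 3 standard errors plus
the add-one bias allowance); curveball uniformity against the six
permutation matrices of the (1,1,1)/(1,1,1) margin class by χ² at 10⁴
samples.  These sizes keep the full suite under a minute while leaving
the Monte-Carlo standard errors small enough to detect real defects.

## Known limitations

- Only undirected unipartite backbones; directed variants and
  multigraphs are out of scope.
- The artifact-mode projection of a bipartite network is obtained by
  transposing the incidence matrix, not by a separate code path.
- Dense matrix storage bounds practical problem sizes to tens of
  thousands of nodes; the algorithms themselves are not the
  bottleneck for the statistical models (the per-dyad Poisson-binomial
  DP is).
- The model-suggestion heuristic cannot distinguish an unweighted
  unipartite graph from a binary symmetric projection; it follows the
  stated value-based rule only.
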