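# Methods

## Model and assumptions

The pipeline treats a battery of categorical questionnaire items (here 5
dichotomous PTSD-screen items scored 0/1 and 20 four-point depression
items scored 1–4) as discretizations of a latent multivariate normal
vector with unit variances. Conditional dependence among the latent
scores is encoded by the precision matrix Θ of a Gaussian graphical
model: Θ<sub>ij</sub> = 0 means items i and j are independent given all
other items, and the edge weight reported for a pair is the partial
correlation −Θ<sub>ij</sub>/√(Θ<sub>ii</sub>Θ<sub>jj</sub>).

This latent-Gaussian assumption is what justifies the polychoric
correlation input stage, and it is exactly the generative model of the
synthetic-data module, which makes the estimator-consistency checks
well-posed: the generator's partial correlations are the estimand.

## Estimation stack

**Polychoric correlations.** Two-step maximum likelihood: thresholds are
the standard-normal quantiles of the marginal cumulative proportions
(with a 0.5/n continuity correction when an extreme category is empty),
then the latent correlation maximizes the bivariate-normal cell
likelihood over (−1, 1). The bivariate normal CDF is evaluated through
Owen's T function (fast, vectorized, accurate in the tails). Estimates
are clamped to ±0.999 so downstream matrices stay invertible; boundary
solutions (empty off-diagonal cells) snap to the clamp. Pairwise
matrices that are not positive definite are repaired by Higham
alternating projections (unit diagonal, eigenvalue floor 1e−8).
Spearman and Pearson correlations are available as cheaper alternatives
and are used by the resampling-heavy layers when runtime matters; every
output records which method produced it.

**Graphical lasso.** Block coordinate descent on the covariance (one
lasso subproblem per column), unpenalized diagonal, warm starts along a
log-spaced path of 100 penalties from λ_max = max |S<sub>ij</sub>| down
to 0.01·λ_max (both configurable). Convergence is verified against the
stationarity conditions; the selected model's KKT residual is required
to be ≤ 1e−4. Entries with |Θ<sub>ij</sub>| < 1e−10 count as absent
edges. The hot loop compiles with numba when available and falls back
to pure Python otherwise.

**EBIC selection.** EBIC = −2ℓ + E·log n + 4·E·γ·log p with
ℓ = (n/2)(log det Θ − tr(SΘ)) (constants dropped — only differences
matter), E the number of nonzero unordered off-diagonal pairs of the
estimated precision (no post-selection refit), and γ = 0.5, the
conservative convention for symptom networks. Ties resolve toward
larger λ (the sparser model).

A property worth knowing: with γ = 0.5 the false-positive edge rate is
small for genuinely sparse truths (≈ 2% at 10% density, n = 5000) but
*plateaus* rather than vanishing at moderate densities (≈ 8% at 20%
density, even at n = 20000), because the selection is constrained to the
lasso path: weak spurious edges enter the path before the shrinkage bias
on strong true edges is resolved. This is a property of path-constrained
EBIC selection, not of the solver (which is cross-checked against an
independent implementation and a generic convex optimizer).

## Centrality and predictability

Expected influence is the one-step signed row sum of the weight matrix;
bridge expected influence restricts the sum to edges leaving a node's
community, and the per-target-community decomposition satisfies
EI = bridge EI + within-community EI exactly. Both raw and
z-standardized (sample SD) values are reported, since conventions differ
between published tables.

Predictability is a nodewise-regression approximation of the
mixed-graphical-model variance-explained index: for ordinal items, the
OLS R² of the item on its selected network neighbors; for binary items,
the normalized classification accuracy
(accuracy − modal baseline)/(1 − modal baseline) of a logistic
regression, with a weak ridge fallback (penalty 1e−4) under separation.
Isolated nodes score 0 by definition. Values are floored at 0 and lie in
[0, 1]. The divergence from the full mixed-model index is deliberate and
the index is labelled "nodewise predictability" accordingly.

## Community detection

Walktrap agglomeration: communities start as singletons, and adjacent
pairs merge to minimize the increase in mean squared t-step random-walk
distance (t = 4), with Ward-style updates of community walk profiles.
Transition probabilities use the *lazy* walk P = (I + D⁻¹A)/2 — plain
t-step probabilities suffer a parity artifact on near-bipartite
subgraphs (a pendant pair can look maximally distant at even t), and the
lazy walk matches the reference implementation's behavior. Random walks
need nonnegative weights, so walk probabilities and modularity use
absolute edge weights by default (`negative="truncate"` drops negative
edges instead, to probe sensitivity). The reported partition is the
dendrogram cut maximizing Newman weighted modularity, ties toward fewer
communities; isolated nodes are singletons; all tie-breaks are by lowest
node index, so results are deterministic given the matrix.

## Resampling diagnostics

Edge accuracy: nonparametric bootstrap (rows resampled with replacement,
full pipeline re-run per replicate), percentile 95% CIs from empirical
quantiles with linear interpolation (not BCa — simple and conventional).
Replicates whose resample turns an item constant are dropped and logged;
more than 10% dropped aborts. Difference tests declare two edges (or two
node EIs) different when the percentile CI of the replicate-wise
difference excludes zero.

Stability: case-dropping bootstrap over a default grid of drop
proportions 0.05–0.75 in steps of 0.10, 50 subsamples per level, Pearson
correlation between subsample EI and full-sample EI. The CS-coefficient
is the largest grid proportion at which ≥ 95% of the level's
correlations reach 0.7 (0 if none qualifies); ≥ 0.25 is conventionally
acceptable, ≥ 0.5 preferred. Replicate counts default to B = 1000 for
edge CIs and 50 per drop level; seeds are explicit arguments everywhere.

## Two-group comparison

The permutation test pools both groups' rows in a canonical (sorted)
order and reassigns them to groups of the original sizes — the canonical
order plus smaller-group-first assignment makes every statistic and
p-value exactly invariant to swapping the group labels. Statistics:
S = |difference in global strength| (sum of absolute edge weights),
M = max absolute edge difference, and per-node C = |EI difference|.
P-values use the add-one convention p = (1 + #{perm ≥ obs})/(1 + B), so
the smallest attainable p is 1/(B+1). Per-edge tests run only after an
omnibus (S or M) significance at α = 0.05 — mirroring the convention of
testing edges only when the omnibus rejects — with Holm adjustment; a
flag forces them. Permutations that make an item constant within a group
are redrawn (≤ 10 retries).

## Synthetic-data generator

The generator is the latent-Gaussian copula the estimator assumes. A
ground-truth precision matrix is built directly from target partial
correlations: a random edge set at the requested density, magnitudes
uniform in a weight range (default 0.2–0.4 for generic use), a 10% share
of negative edges, unit diagonal. If the resulting matrix is not
comfortably positive definite, all partials shrink by a common factor
until the smallest eigenvalue reaches 0.05; the final unit-variance
rescale is diagonal and therefore leaves partial correlations unchanged.
Named edges can be pinned to exact final partials by a fixed-point
refinement.

The packaged survey-scale design uses 25 nodes with the published
per-item means/SDs as discretization targets (category proportions
moment-matched on the probability simplex; binary rates matched
exactly), n = 1781 with an optional 624/1157 two-group split, truth
density 140/300, partial-correlation targets uniform in 0.05–0.25, and
the flashback–avoidance edge pinned at 0.46. These choices were
calibrated once against the published descriptives and then frozen; at
survey scale the synthetic cohort reproduces the reported study's
character (screening prevalences ≈ 8%/36%, strongest edges ≈
0.45/0.36/0.34, three walktrap communities, mean predictability ≈ 25–35%
depending on the draw, CS-coefficient 0.75).

What the generator does *not* emulate: item-level non-normal latent
structure (skew beyond thresholding), local dependence violations,
response styles, missingness, or any causal dynamics. Passing tests
therefore demonstrate internal consistency of the estimation stack under
its own assumptions — not robustness to the ways real survey data
violate them.

## Problem sizes in the test suite

Resampling and permutation tests re-estimate networks thousands of
times, so the suite instantiates them at small node counts with the
Pearson/short-path pipeline configuration (5–15 nodes; e.g. the null
calibration of the S test uses 200 replicates × 250 permutations at
n = 300 per group), while single-fit checks run the full polychoric
stack at survey scale. The type-I error of the S test under the null
lands within 0.05 ± 0.04.

## Known limitations

- The polychoric stage assumes non-degenerate margins; constant items
  are rejected rather than imputed around.
- EBIC-over-the-lasso-path is not model-selection consistent at moderate
  densities (see above); reported edge counts at survey scale exceed the
  true count, with weak spurious edges.
- Predictability for binary items with very rare endorsement is noisy
  (modal baseline near 1).
- The walktrap cut optimizes modularity over dendrogram levels only, not
  over all partitions; on well-separated graphs (checked exhaustively up
  to 8 nodes) it attains the global optimum.
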