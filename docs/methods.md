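# Methods

## The model

`grmec` clusters n cells measured in m omics views (e.g. RNA + surface
protein from CITE-seq, or RNA + ATAC) by jointly optimizing four coupled
factors:

* **W** (n × k, nonnegative) — one consensus low-dimensional cell
  representation shared by all views, from a weighted joint NMF
  `Σ_v w_v ‖X^v − W V^v‖_F²` with per-view bases **V^v** (k × p_v).
* **S** (n × n, nonnegative symmetric) — a consensus co-cluster affinity
  learned from a q × m grid of base clustering results: each base labeling
  P^rv becomes a binary indicator S^rv (1 where two cells share a label),
  and S minimizes `Σ_rv α_rv ‖S − S^rv‖_F²`.
* **H** (n × C, nonnegative, unit row sums) — the soft cluster indicator.
  Two graph-Laplacian penalties tie everything together:
  `λ1 · tr(Wᵀ L_H W)` (cells that H co-clusters are pulled toward nearby
  rows of W, with L_H the Laplacian of S_H = H Hᵀ) and
  `λ2 · tr(Hᵀ L_S H)` (cells with high consensus affinity are pulled
  toward the same cluster).

The view weights `w_v = 1/(2‖X^v − W V^v‖_F)` and ensemble weights
`α_rv = 1/(2‖S − S^rv‖_F)` are self-tuned inverse residuals, so a noisy
view or a poor base result automatically counts less; λ1, λ2, k and C are
the only free parameters. Hard labels are the row argmax of H (ties go to
the lowest column index).

All four factors are updated by alternating multiplicative rules, one
sweep being W → {V^v} → S → H (+ row unitization) → weights → objective.
Multiplicative updates preserve nonnegativity and, for these coupled
quadratic subproblems, never increase the joint objective; the
self-tuned weights keep the trace monotone as well because each weight
formula is the stationary point of the half-quadratic majorizer of the
corresponding root term. The loop stops when the relative objective
change falls below `tol` (default 1e-6) or after `max_iter` (default
200) sweeps.

### The W update and the Laplacian sign issue

The gradient-derived multiplicative rule for W would place the full
Laplacian `λ1 L_H W` in the denominator. `L_H = D_H − S_H` has negative
off-diagonal entries, which can drive iterates negative. We use the
standard graph-regularized-NMF split instead — `λ1 S_H W` joins the
numerator and `λ1 D_H W` the denominator — which has the same fixed
points and provably keeps every iterate nonnegative. This is the one
place where the implemented rule is not literally the naive gradient
form, and it is the conventional resolution.

### Initialization is load-bearing

The alternating dynamics have two families of attractors. In the wanted
one, H is (near) one-hot over cluster blocks, S_H is block-diagonal, and
the λ1 coupling only smooths W *within* clusters — a self-consistent
configuration that sharpens H further. In the degenerate one, H's rows
equalize: after row unitization, column-constant perturbations of an
all-rows-equal H survive the multiplicative update with factor exactly 1
while cluster-structured perturbations decay at the random-walk rate of
`D_S⁻¹S`, so the argmax lands in a single column; S_H then turns dense,
W's rows flatten to a common mean, and the partition is lost. Random
uniform starts land in the degenerate basin essentially always (we
verified this across a λ grid).

The default initialization (`init="warm"`) therefore starts structured:

* W and V^v are drawn uniform at the data scale (`E[(W V)_ij]` matches
  the pooled mean of X, the convention scikit-learn's NMF also uses) and
  refined by `pretrain_sweeps` (default 30) plain multiplicative NMF
  sweeps with λ1 = 0, so W carries cluster structure before the graph
  couplings switch on;
* H is k-means on the mean base co-cluster matrix, blended with the
  uniform simplex point (0.8 one-hot + 0.2 uniform) so no entry is
  zero-locked by the multiplicative update;
* S is symmetrized uniform noise (or the mean of the S^rv with
  `warm_start_S=True`).

`init="random"` retains the fully random scheme for studying the raw
dynamics. Objective monotonicity holds under either choice.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `lambda1` | 0.1 | W ↔ H coupling strength (unitless trade-off) |
| `lambda2` | 0.01 | S ↔ H coupling strength |
| `n_components` (k) | 50 | latent dimension of W; capped at the smallest view dimension at fit time |
| `n_clusters` (C) | — | number of clusters, 2 ≤ C ≤ n |
| `tol` | 1e-6 | relative objective change that stops the loop |
| `max_iter` | 200 | sweep budget |
| `denom_floor` / `residual_floor` | 1e-10 | floors (as `max(x, floor)`) for multiplicative denominators and for the weight residuals, which are otherwise undefined at an exact fit |

λ1 and λ2 are the defaults of the recommended operating point; they
interact with the scale of the data (the graph terms compare O(1)
affinities against data-scale residuals), which is why views should go
through `preprocess` (library-size + log1p for counts) before fitting.

## Preprocessing

* **Cell filtering**: drop cells whose zero fraction strictly exceeds
  `zero_fraction_cutoff` (default 0.95 — only near-empty cells).
* **Normalization**: `libsize-log1p` scales each cell to the view's
  median library size and applies log(1+x); protein (ADT) panels default
  to `none` because they are small and already comparable.
* **HVG selection**: mean-binned standardized dispersion on log1p values
  (variance/mean per feature, z-scored within 20 equal-frequency mean
  bins), top `n_hvg` (default 1000) kept. Zero-dispersion features rank
  last; ties break by higher mean, then lexical feature id, so selection
  is fully deterministic.

ATAC peak matrices are accepted as provided; peak calling/selection is
out of scope.

## Base clusterings

Three seeded scikit-learn-backed clusterers are built in (`kmeans-pca`,
`spectral-knn`, `agglomerative-ward`; PCA dimension 30 capped at
min(n, p) − 1), applied to each view independently to form the q × m
grid. Externally produced label CSVs can be ingested instead — only
co-membership matters to the model, so base results may use any number
of clusters.

## The synthetic-data generator

`simulate_multiomics` draws the structure the factorization assumes: a
planted C-way partition; cluster latent means = U(0.1, 0.5) baseline plus
`separation` (default 2.0) on cluster-specific coordinates of a k_true=8
latent space; per-view **sparse** nonnegative loadings (each factor
drives ~30% of features plus a 0.02 baseline) so cell types differ in
*which* features they express — a dense basis would make cluster identity
ride on library size, which normalization removes by construction; means
scaled to `count_scale` (default 2000) per cell; Poisson (optionally
negative-binomial) sampling; multiplicative lognormal noise
(`noise_sd`, default 0.1); independent dropout zeroing (default 0.3).
All draws flow from one seed through named per-component streams, so
adding a view never changes earlier views. `simulate_base_set` corrupts
the planted truth independently per cell at a given error rate per
(method, view) grid entry.

What the generator does **not** emulate: realistic mean–variance
relationships of specific protocols, batch effects, doublets, ambient
contamination, or the long-tailed peak sparsity of real ATAC data.
Passing the planted-partition tests shows the optimizer recovers the
structure its own model assumes under count noise and dropout — not
performance on any real dataset.

## Evaluation

ARI (permutation-model adjusted Rand index) and NMI (mutual information
normalized by the arithmetic mean of entropies; 0 when either partition
is a single cluster) are computed via scikit-learn; the test suite
re-derives both from first-principles contingency-table oracles. Marker
ranking is a one-vs-rest two-sided Wilcoxon rank-sum test per feature
(normal approximation with tie and continuity corrections, vectorized
over features; all-tied features get p = 1), ranked by ascending p-value
with ties broken by higher in-cluster mean. No multiple-testing
correction — the per-cluster ranking is the deliverable.

## Numerical and performance notes

* Denominators are floored with `max(x, 1e-10)`, not by adding a
  constant, so algebraic cancellations (e.g. one S-update with a single
  base result reproducing S^11) are exact.
* Row unitization of H resets any all-zero row to uniform 1/C with a
  warning (this happens systematically when λ2 = 0, where the H
  numerator vanishes).
* S is a dense n × n matrix; practical ceiling around n ≈ 10⁴. One sweep
  costs O((Σ_v p_v) n k + n²(k + C)); the n² elementwise work is
  bandwidth-bound, so `update_S`, the α-weights and the symmetrization
  are tiled into cache-sized row slabs.
* D^h and D^W are recomputed from the current H and W each sweep; the
  `D^W H` product is expanded through row norms and Gram products so the
  H update needs no n × n intermediate.
* Determinism: identical seeds give bit-identical fits; per-view base
  clusterer seeds derive from crc32 of the view name, stable across
  processes.

## Problem sizes used by the checks

The planted-partition study runs at n=300 cells, C=4 clusters, m=2 views
with (500, 200) features, q=3 base methods at 10% label corruption, and
k capped at 20 — small enough to iterate quickly while keeping the n² 
consensus machinery fully engaged. The scaling check times single sweeps
at n ∈ {250, 500, 1000, 2000}.

## Known limitations

* The optimizer refines rather than discovers: with adversarially bad
  base results *and* uninformative views it keeps whatever the warm
  start proposes. This mirrors the model's design — the ensemble is the
  clustering signal's backbone.
* The λ1 coupling has a scale degeneracy (shrinking W while inflating
  V^v leaves the reconstruction unchanged and sends the graph penalty to
  zero); the warm start parks the iterates in a useful region but
  nothing anchors the W scale asymptotically.
* No automatic selection of C, no sparse-S path, no GPU, no
  convergence-proof machinery.
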