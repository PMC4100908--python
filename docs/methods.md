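# Methods

This note documents the models and procedures implemented in `braincbir`, the
parameter choices that matter, and what the synthetic phantoms do and do not
establish about real MR data.

## Problem setting

The task is category retrieval: a 2-D T1-weighted contrast-enhanced MR slice
with a rectangular ROI around a brain lesion queries a database, and slices
whose tumors share the query's pathological category (meningioma, glioma,
pituitary tumor) should rank first. Two observations drive the design. First,
the three tumor types differ in the *spatial layout* of intensity inside and
around the lesion (homogeneous mass against a bright dural rim; heterogeneous
mass with necrotic core and edema halo; homogeneous mass near a distinct
bright landmark), so a spatial pooling scheme adapted to the data should beat
a fixed symmetric one. Second, Euclidean distance on pooled BoVW histograms
weights all visual words equally, so a supervised Mahalanobis metric should
close part of the gap between visual features and diagnostic categories.

## Intensity normalization

MR intensities are scanner- and session-relative. Each slice is rescaled by a
quantile min–max map: with `q1`, `q99` the 0.01 and 0.99 quantiles (linear
interpolation between order statistics, computed over the whole image or a
provided mask), the output is `clip((I − q1)/(q99 − q1), 0, 1)`. A constant
region raises a degenerate-input error rather than producing NaNs. Bias-field
correction (N3/N4) is deliberately out of scope: it is standard external
preprocessing, and the phantoms' mild polynomial bias (≤ 10%) is absorbed by
quantile scaling. Quantiles are per-slice, since the data model is a
collection of independent 2-D slices.

## BoVW features

Raw `w×w` patches (default `w = 7`) are taken densely (stride 1 by default;
desk-scale studies use stride 2) inside the ROI, flattened row-major, with no
mean subtraction — for contrast-enhanced lesions the absolute intensity level
is itself discriminative. The dictionary is k-means with k-means++
initialization, one seeded run, 100 iterations, tolerance 1e-6. Soft
assignment uses weights `∝ exp(−‖x − word‖²/(2σ²))` on the `K = 5` nearest
words; the default kernel width σ is the median nearest-neighbor distance
among the dictionary words, which adapts to the dictionary's scale without a
free parameter. Computing the weights with a max-shift makes the σ → 0 limit
reproduce hard assignment exactly. Pooling is the p-norm statistic
`((1/n) Σ cᵖ)^(1/p)`; `p = 1` is average pooling and `p = ∞` max pooling (the
retrieval default).

## Learned partition

All cuts live in the unit square `[0,1]²`: a patch center at ROI-local
`(row, col)` maps to `x = (col+0.5)/W`, `y = (row+0.5)/H`. This makes one
learned partition transferable across ROIs of different pixel sizes and makes
features invariant to pure rescaling of the sampling grid.

A cut is a line in normal form `x·cosθ + y·sinθ = r`, θ ∈ [0, π); points with
projection ≤ r fall on side A (boundary included — a fixed tie rule needed
for determinism). The objective of a candidate cut of region R is

    J(θ, r) = Σ_{images} D_SKL(h_A, h_B) − λ · N · |S_A − S_B|

with `D_SKL(p, q) = KL(p‖q) + KL(q‖p)` on histograms smoothed by adding
`eps = 1e-10` per bin and renormalizing (finite divergence on disjoint
supports), `S_A`, `S_B` the geometric sub-areas (shapely polygon clipping;
areas are the shoelace values), and `N` the number of training images.
Histograms entering the divergence are average-pooled (`p = 1`),
L1-normalized soft codes — proper distributions, as KL requires — even though
the final retrieval features default to max pooling; the max-pooled vector is
not a distribution and its "KL" would not be a divergence. An empty side in
one image contributes a uniform histogram.

Two guards reject the degenerate splits that raw divergence maximization
favors (a sliver with a handful of patches has a near-singular histogram and
an inflated divergence): a hard minimum leaf area of 0.02 unit-square units
(candidates below it score −∞), and the area-balance term with default
λ = 1/S(R) for the region R being cut, which makes the penalty scale-free in
[0, 1·N] regardless of how deep in the recursion the cut happens.

Optimization per cut: a coarse grid (8 angles × 9 offsets spanning the
region's projected support) seeds alternating coordinate descent — try
θ ± Δθ holding r, then r ± Δr holding θ; accept only improvements; halve the
step when neither direction improves; stop when Δθ < π/1800 and Δr < 1e-4 or
after `t_max` sweeps (default 1000; the steps collapse after a few dozen
sweeps on desk-scale problems). Accepted objectives are non-decreasing by
construction, which the tests assert per iteration. The greedy outer loop
applies `k` cuts (default 9 → 10 regions), each to the current maximum-area
leaf, ties to the earliest-created leaf. The optimization is local — different
seeds or initial grids can end in different local optima; this is inherent to
the alternating scheme and is why the grid initializer and tie rules are
pinned.

The spatial-pyramid baseline pools over uniform 2ˡ×2ˡ grids for levels
0..L−1 (21 regions for L = 3).

## REML

Distance is `‖L(x_i − x_j)‖²` with `L ∈ ℝ^{d×D}`, `d = 3` by default — a
pseudo-metric (rank deficiency is allowed and intended; Fig.-style 2-D/3-D
embeddings of the three classes are linearly separable when the features
are). For a query with relevant set S and irrelevant set D, the smoothed
per-query loss is

    ℓ = Σ_{i∈S} softplus(g̃_i),   g̃_i = (1/η)·ln Σ_{j∈D} exp(η·(d_i − d_j)),

with η = 1. The log-sum-exp tends to the hard gap `max_j (d_i − d_j)` as
η → ∞ and equals it exactly for |D| = 1; softplus(g̃) tends to the 0/1 rank
error as margins grow. The objective averages ℓ over queries (so the
regularization weight γ = 1e-4 keeps one meaning regardless of training-set
size) and adds `γ·tr(LᵀL) = γ‖L‖_F²`.

The gradient uses the chain rule through `∂d_j/∂L = 2L u_j u_jᵀ`
(`u_j = x_q − x_j`); since the log-sum-exp weights `softmax_j(−η d_j)` do not
depend on the relevant item i, the per-query gradient collapses to a single
weighted outer-product sum, computed as two small matrix products. Agreement
with central finite differences to better than 1e-4 relative error across
randomized shapes is part of the acceptance suite.

Training: `L₀` comes from LFDA (below); each SGD iteration samples one
training item uniformly as the query against all remaining training items
(same-class = relevant, mirroring the evaluation protocol); the step size is
`α_t = α₀/(1 + t/t_max)` with the scale-free
`α₀ = 1e-3·(‖L₀‖_F + 1)/(‖∇J(L₀)‖_F + 1)`. The objective is monitored every
50 iterations and the best monitored iterate is returned, so the result never
scores worse than the initializer. Non-finite updates are rejected and halve
the step scale; persistent failure raises. All randomness flows from one
seeded generator.

LFDA builds the locality-weighted within/between-class scatter pair with the
local-scaling affinity `A_ij = exp(−‖x_i − x_j‖²/(σ_i σ_j))`, σ_i being the
distance to the 7th nearest *distinct* neighbor (the distinct-value rule
makes the bandwidth, and hence the projection, invariant to duplicated
samples). Rows of `L₀` are the top-d generalized eigenvectors of
`(S_b, S_w)`; when `S_w` is numerically singular — always true when the
feature dimension exceeds the sample count — a ridge of 1e-9·I is added with
a warning, and eigenvector signs are fixed deterministically.

## Retrieval evaluation

Rankings sort by ascending distance with ties broken by ascending database
index. AP is the mean of Prec@rank over ranks holding relevant items; mAP
averages over queries; queries with no relevant item in the pool are excluded
and counted. Folds are assigned at the patient level (shuffled patients dealt
into near-equal groups, sizes differing by at most one), and every stage —
dictionary, partition, metric — is fit on the training split only; test
images only query. PR curves are macro-averaged over queries at a fixed
21-point recall grid using the max-precision-at-recall≥r interpolation.

## Phantom generator

Phantoms emulate the *structure* of a clinical slice archive, not its
appearance: three classes distinguished purely by spatial layout inside the
ROI, multiple slices per synthetic patient (shared lesion geometry with
per-slice shift/scale/rotation jitter), additive Gaussian noise
(sd 0.02 of the intensity range), and a smooth multiplicative second-order
polynomial bias (amplitude 0.10) standing in for coil inhomogeneity. Lesions
are smooth polar blobs `R(φ) = r₀(1 + a₂cos(2φ+ψ₂) + a₃cos(3φ+ψ₃))` with
sigmoid edges — hand-checkable geometry with controllable class separation.
Defaults (10 patients per class, 3 slices each, 64×64 images) are a
desk-scale stand-in for a multi-hundred-patient archive. Output is 16-bit
PNG plus a CSV metadata table (path, patient id, label, ROI box), both
lossless and inspectable.

What passing on phantoms does **not** show: robustness to real MR artifacts
(motion, partial volume, view mixing across transverse/sagittal/coronal
planes), to inter-scanner intensity distributions beyond a smooth bias, or to
imprecise ROI placement beyond the simulated random margin. Absolute phantom
mAP values are not comparable to clinical-archive results; only the *ordering
of method variants* (learned metric vs Euclidean, learned partition vs fixed)
is the claim the test suite checks.

## Numerical choices and degenerate inputs

- Histogram smoothing `eps = 1e-10` per bin before renormalization; the
  closed form for disjoint supports is tested at an explicit `eps = 1e-12`.
- Leaf polygons are maintained by half-plane clipping; areas must sum to 1
  within 1e-9 after every cut (asserted).
- Hard-assignment ties go to the lowest word index; boundary points go to
  cut side A; equal-area leaves split earliest-created first; ranking ties
  break by ascending database index. Every tie rule is deterministic so that
  identical configs and seeds give byte-identical artifacts.
- Constant images, empty masks, ROIs smaller than the patch, single-class
  training sets, and queries without relevant items raise typed errors
  instead of propagating NaNs.

## Desk-scale study sizes

The cross-validated efficacy study in the test suite uses 30 synthetic
patients (3 slices each), V = 100, stride 2, k = 4, d = 3, five patient-wise
folds and five seeds, with partition `t_max = 60` and REML `t_max = 300` —
sizes at which the coordinate-descent steps have collapsed and the monitored
REML objective has plateaued, so larger iteration caps change nothing but
runtime. The acceptance script's structural computation uses 24 phantom
images and a V = 50 dictionary; the leaf count of the learned partition is
invariant to these sizes by construction (k cuts always yield k+1 leaves
unless no feasible cut exists, which the minimum-leaf-area geometry rules out
at k = 9).

## Known limitations

- The learned metric is a single global linear projection; classes that are
  not linearly separable after pooling would need local or kernel metrics.
- Partition learning optimizes a non-convex objective by greedy local search;
  solutions are local optima and depend on the pinned initialization.
- The pipeline is strictly 2-D; volumes would require plane cuts and
  resolution normalization.
- Histogram intersection–style alternatives to KL, curved cuts, and
  per-class partitions are out of scope.
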