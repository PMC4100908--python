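# braincbir

Content-based image retrieval (CBIR) for 2-D brain-tumor MR slices. Given a
query slice with a rectangular region of interest (ROI) around the lesion, the
system ranks a database of labeled slices so that tumors of the same
pathological category (meningioma, glioma, pituitary tumor) come first. It is
aimed at researchers building category-retrieval baselines for lesion imaging,
and ships a seeded phantom generator so the whole pipeline runs and is tested
without clinical data.

## Method

Features are spatially-aware bag-of-visual-words (BoVW) histograms:

1. **Dense raw patches.** Every `w×w` (default 7×7) intensity patch inside the
   ROI of an intensity-normalized slice (1%/99% quantile min–max to `[0,1]`)
   is a local descriptor.
2. **Dictionary + soft coding.** k-means learns `V` visual words; each patch
   gets a kernel-codebook soft code over its `K` nearest words.
3. **Learned spatial partition.** The ROI frame is the unit square. `k` line
   cuts `x·cosθ + y·sinθ = r` are chosen greedily, each splitting the current
   largest region by maximizing

   `Σ_images D_SKL(h_A, h_B) − λ·N·|S_A − S_B|`,

   where `h_A, h_B` are the average-code histograms of the two sides,
   `D_SKL = KL(p‖q) + KL(q‖p)`, and the area term rejects degenerate slivers.
   Each cut is refined by alternating coordinate descent on `(θ, r)`. A fixed
   spatial-pyramid partition (1×1 + 2×2 + 4×4) is included as the baseline.
4. **Pooling.** Soft codes are max-pooled (p-norm pooling, `p=∞`; `p=1` gives
   average pooling) per region and concatenated into an `m·V` feature.
5. **Rank-error metric learning (REML).** Retrieval distance is the squared
   Mahalanobis form `d(x_i, x_j) = ‖L(x_i − x_j)‖²` with a learned `d×D`
   projection. For a query with relevant set `S` and irrelevant set `D`, the
   loss smooths the rank error `Σ_{i∈S} 𝟙[max_{j∈D}(d_i − d_j) > 0]` by a
   log-sum-exp max and a logistic (softplus) indicator:

   `ℓ = Σ_{i∈S} ln(1 + exp(g̃_i))`, `g̃_i = (1/η)·ln Σ_{j∈D} e^{η(d_i − d_j)}`,

   minimized over `L` (objective: mean loss over queries + `γ·tr(LᵀL)`) by
   stochastic gradient descent from an LFDA (local Fisher discriminant
   analysis) initialization.

Evaluation is mean average precision (mAP), Prec@n and precision–recall
curves under patient-wise cross-validation: all slices of a patient stay on
one side of every train/test split, and each test slice queries the training
database only.

## Worked example

```python
from braincbir import PhantomConfig, RunConfig, generate_phantoms, evaluate_cv

records = generate_phantoms(
    PhantomConfig(n_patients_per_class=5, slices_per_patient=3, seed=0)
)
cfg = RunConfig(V=100, stride=2, k=4, partition_t_max=60, metric_t_max=300,
                monitor_interval=50, n_folds=5, seed=0)
report = evaluate_cv(records, cfg)
print(f"mAP = {report.map_mean:.3f} +/- {report.map_sd:.3f}")
for n, (m, s) in report.prec_at_n.items():
    print(f"Prec@{n} = {m:.3f} +/- {s:.3f}")
```

prints (about one minute on one CPU):

```
mAP = 0.943 +/- 0.080
Prec@5 = 0.911 +/- 0.130
Prec@10 = 0.867 +/- 0.128
```

i.e. on a 45-slice phantom set (15 patients, 3 classes), features pooled over
the 5 learned regions (`(k+1)·V = 500` dimensions) with the REML metric rank
same-category slices near the top: averaged over queries and folds, ~94% of
the precision mass sits on relevant items, and ~9 of the first 10 returned
slices share the query's tumor class. Per-class mAP is also in
`report.per_class` (glioma 1.000, meningioma 0.952, pituitary 0.878 here).

The same pipeline is scriptable from the shell:

```sh
braincbir simulate --config phantom.yaml --out data/
braincbir run --meta data/metadata.csv --config run.yaml --out index/
braincbir evaluate --meta data/metadata.csv --config run.yaml --out eval/
braincbir query --image data/P0000_s0_00000.png --roi 12,10,40,40 --index index/ --topn 10
```

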