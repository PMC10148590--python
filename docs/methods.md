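# Methods

This note documents the models, defaults and numerical choices behind
`pseudospace`, and what the simulation benchmark does and does not
establish.

## Problem setting

Two expression matrices over a shared gene space: single-cell RNA-seq
(source, n₁ cells, no positions) and a spatial reference (target, n₂
spots or cells with 2-D coordinates), assumed to profile the same tissue
and cell-type repertoire. The goal is a coordinate estimate for every
single cell, plus a clustering that can use those coordinates.

## Harmonization and normalization

Genes are restricted to the lexicographically sorted intersection of the
two gene sets; nothing is imputed, because the joint kernel requires an
identical feature space. Counts are scaled per observation to a fixed total
(default 1e4, the common single-cell convention) and log(1+x)-transformed.
Optionally only the top `n_hvg` (default 2000) most variable genes — judged
on the log-normalized single-cell side — are kept, which bounds the kernel
cost. Datasets already tagged as normalized pass through unchanged, making
the step idempotent. All-zero observations are retained (as zero rows) with
a warning rather than dropped, so external label tables stay aligned.

## Transfer component analysis

The batch effect is modeled as a distribution shift and measured by the
kernel maximum mean discrepancy. With the joint kernel K over all n = n₁+n₂
observations, MMD² = tr(KL), L = vvᵀ, vᵢ = 1/n₁ or −1/n₂ by domain. The
transform W minimizes tr(WᵀKLKW) + μ·tr(WᵀW) subject to WᵀKHKW = I and is
obtained from the m smallest eigenpairs of the pencil

    (I + μ·KLK) w = λ (KHK + ridge·I) w,

solved with a symmetric-definite generalized eigensolver after explicit
symmetrization of both sides. Choices:

* **Kernel**: linear by default (K = XXᵀ); it keeps the small-instance
  oracles exact, is the cheapest positive semi-definite choice, and worked
  indistinguishably from RBF on the simulated benchmark. RBF with a
  median-heuristic bandwidth (γ = 1/(2·median pairwise distance²)) is
  available.
* **μ = 1, m = 50** by default; m mirrors the usual top-50-PCs convention
  for expression data.
* **Ridge**: KHK is always rank-deficient (H centers), so the right-hand
  side gets a ridge of 1e-8·tr(KHK)/n, escalated tenfold (to at most
  1e-2 on that relative scale) if the factorization fails. The μ·tr(WᵀW)
  regularizer in the objective addresses the numerator, not this inverse.
* **Normalization**: each eigenvector is rescaled so wᵀ(KHK)w = 1 (the
  constraint), or unit-normalized with a warning if it lies in the null
  space of KHK.
* **Scale cap**: above 5000 joint observations the target side is uniformly
  subsampled (seeded) to 5000 − n₁ anchor rows for the kernel; embeddings
  for all rows are recovered by the Nyström extension K_new·W.

A note on the eigenproblem's form: the stationarity condition is written
here (and solved) as (I + μKLK)W = KHK·W·Z. Deriving it from the stated
objective gives (KLK + μI)W = KHK·W·Z instead; the two differ only by a
rescaling of μ and of the eigenvalues, not in which subspaces are optimal,
so the printed form is used as-is.

## Coordinate regression

The map from target latent features to coordinates is a perceptron with one
hidden layer of 128 units (ReLU by default, sigmoid available), trained
with Adam (learning rate 1e-3, betas 0.9/0.999) under MSE loss — the model
family and optimizer are fixed; the schedule is this package's choice:

* **Coordinate scaling**: per-axis min-max to [0, 1] before training, with
  the inverse transform recorded, so loss magnitudes are comparable across
  platforms whose coordinate units differ by orders of magnitude.
  Predictions are reported in reference units.
* **Epochs/batching**: 1000 epochs of seeded, shuffled mini-batches of 128.
  Full-batch training is available but not the default: it performs only
  `epochs` optimizer steps, which demonstrably underfits (training RMSE ~2.7
  spatial units on a 20×20 field whose within-population scatter is 1;
  spatially displaced subclusters collapse onto their parents). Shuffling
  with a fixed seed keeps runs bit-reproducible, so the determinism that
  motivated full-batch training is preserved.
* Training aborts with an informative error if the loss goes non-finite.

## Space-informed clustering

The expression graph is a union-symmetrized KNN graph (k = 20) on the top
50 principal components of the normalized single-cell matrix. Spatial edge
weights *replace* any expression-derived weight — the topology already
encodes expression similarity. Two strategies:

* **Gaussian** (default): w = exp(−d²/2l²) with d the Euclidean
  pseudo-space distance *in reference coordinate units* and l = 20. The
  length scale is meaningful only relative to the coordinate units: the
  simulated field is 20×20, so l = 20 is the field width. (Min-max-scaled
  coordinates live in [0,1]², where l = 20 would make every weight
  indistinguishable from 1; distances are therefore taken in the reference
  frame, and l is exposed as a user parameter for real tissues.)
* **Hop-based**: w = 1/(α + d) + β (α = β = 1) with d the hop distance on
  a pseudo-space KNN graph (k = 20), capped at 6 (unreachable pairs get the
  cap). This variant is scale-free in the coordinates.

Leiden (RB-configuration modularity, seeded, iterated to convergence)
partitions the weighted graph. When a target cluster count is given, the
resolution is found by bisection on [1e-3, 10] (≤ 40 evaluations), keeping
the partition whose cluster count is closest to the target with ties toward
fewer clusters — benchmarks conventionally fix the cluster count to the
annotated number of cell types. KNN symmetrization is by union (the mutual
variant drops edges for boundary cells).

## Paired simulator

A gamma-Poisson generator in the Splatter style, re-specified here as an
explicit stand-in (distributions and defaults below are this package's
choices, not recovered settings of any external tool):

* Gene baseline means ~ Gamma(shape 0.6, rate 0.3).
* Populations (default 5, equal allocation unless a proportion vector is
  given) receive DE genes with probability 0.2; fold factors are
  2^(±N(1.0, 0.4)) with random sign.
* *Spatial subclusters* (default 0) are carved round-robin from parent
  populations, inherit the parent's DE factors, and add extra DE genes only
  with probability 0.01 — transcriptomically near-identical by design.
* A per-gene batch factor 2^N(0, 0.25) multiplies the single-cell batch,
  emulating the assay shift between modalities.
* Counts are Poisson with per-cell library sizes ~ LogNormal(ln 1e4, 0.25),
  giving negative-binomial marginals across cells.
* Every group gets a spatial center uniform in a 20×20 field; cells
  scatter Normal(center, sd 1). A subcluster's center is re-drawn until it
  is ≥ 5 units (5 spatial sds) from its parent's center: spatial
  separation is the subcluster's defining feature, and an unconstrained
  draw occasionally places it on top of its parent, a configuration no
  method could (or should) resolve. Single-cell coordinates are generated
  the same way around the same centers but kept only as ground truth.
* Default 800 cells per modality (middle of the 500–1500 range the
  benchmark design spans) and 5000 genes.

What the simulator does **not** emulate: dropout beyond Poisson sampling,
outlier genes, trajectories/paths, spot-level mixtures of cell types,
segmentation noise, or spatially smooth expression gradients within a
population. Passing benchmarks here therefore show that the pipeline
recovers *discrete* population geography under a multiplicative batch
effect — not that it handles continuous gradients or deconvolution-grade
spot mixing.

## Evaluation metrics

* **Pairwise-distance PCC**: Pearson correlation of the two upper-triangle
  Euclidean distance vectors (all n(n−1)/2 pairs; an optional seeded pair
  subsample exists for very large n). Invariant to rotation, translation
  and uniform scaling — appropriate because the regression cannot and need
  not recover the global pose of the tissue.
* **ARI**: permutation-model adjusted Rand index.
* **NMI**: mutual information over the arithmetic mean of the entropies
  (a convention had to be fixed); defined as 0 when either partition is
  constant.
* **Normalized group distances**: cross-group pairwise distances min-max
  normalized by the global pairwise-distance range of the embedding
  (again a fixed interpretation of "normalized").
* **Batch separability**: held-out accuracy of a logistic classifier on
  standardized features, 50/50 stratified split — the operational measure
  of how much batch signal a feature space retains.

## Benchmark problem sizes

The reconstruction benchmark runs ten seeded pairs at 800+800 cells with
2000 genes (the reduced-gene variant of the design; the full 5000-gene
variant behaves identically through the 2000-gene highly-variable cut) and
3–6 populations, reporting the median pairwise-distance PCC. The clustering
benchmark runs ten pairs at the simulator's defaults with 2–4 subclusters
and compares space-informed against expression-only Leiden at the matched
cluster count. Batch-effect erasure uses ten pairs at full defaults. These
sizes sit inside the design's stated ranges while keeping a full run on a
laptop-class single core in minutes.

## Known limitations

* The dense joint kernel costs O((n₁+n₂)²) memory; beyond the 5000-row cap
  the Nyström path trades exactness for scale.
* l for the Gaussian weight is expressed in reference coordinate units and
  must be re-chosen for platforms with very different unit scales.
* With very crowded spatial layouts (many populations in a small field)
  the spatial signal degrades gracefully toward the expression-only
  result — distances between overlapping groups carry little information.
* The coordinate regression is a point predictor; no uncertainty is
  attached to pseudo-space positions, and coordinates are strictly 2-D.
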