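# pseudospace

Spatial reconstruction of dissociated single cells from a spatial
transcriptomics reference, and clustering that is aware of the reconstructed
space.

Single-cell RNA-seq (scRNA-seq) resolves cell states at full transcriptomic
depth but destroys tissue context; spatial transcriptomics (ST) keeps the
coordinates but with fewer cells, lower depth, or spot-level mixing.
`pseudospace` is for analysts who have both modalities from the same tissue
and want to (1) place every dissociated cell at a 2-D position in the
reference's coordinate frame — its *pseudo-space* location — and (2) find
cell subpopulations that are transcriptomically near-identical yet occupy
different tissue territories, which expression-only clustering cannot
separate.

## Method

**1. Shared latent features by transfer component analysis (TCA).** The
technical shift between the two assays is treated as a distribution shift
between a source domain X_S (n₁ cells) and a target domain X_T (n₂
spots/cells) over the same genes. With a joint kernel matrix K over the
n₁+n₂ observations, the squared maximum mean discrepancy between the two
domains is tr(KL), where L = vvᵀ with vᵢ = 1/n₁ (source) or −1/n₂ (target).
A transform W ∈ R^{(n₁+n₂)×m} is chosen to solve

    min_W  tr(Wᵀ K L K W) + μ tr(Wᵀ W)    s.t.  Wᵀ K H K W = I,

with H = I − (1/n)11ᵀ the centering matrix: minimize cross-domain
discrepancy while preserving the data's centered-kernel variance. The
columns of W are the eigenvectors of the m smallest eigenvalues of
(KHK)⁻¹(I + μKLK); the latent features are the rows of KW, split into
X′_S and X′_T.

**2. Coordinate regression.** A two-layer perceptron (one hidden layer of
128 units, ReLU, Adam with learning rate 1e-3 and betas 0.9/0.999, MSE
loss) learns [x, y] ~ X′_T on the reference and is applied to X′_S, giving
each single cell its pseudo-space coordinates.

**3. Space-informed clustering.** A k-nearest-neighbor graph built on
principal components of the normalized single-cell expression carries the
transcriptomic topology; each edge (i, j) is re-weighted by pseudo-space
proximity, either by a Gaussian decay w = exp(−d²/2l²) with characteristic
length scale l, or by w = 1/(α + d) + β with d the hop distance on a
pseudo-space KNN graph. Leiden community detection on the re-weighted graph
can then split spatially separated subpopulations that expression alone
merges.

A paired SC/ST simulator (gamma-Poisson counts, population-level
differential expression, a per-gene batch factor between the modalities,
Gaussian spatial placement around uniform centers in a 20×20 field) and an
evaluation suite (pairwise-distance Pearson correlation, ARI, NMI,
normalized group distances) make every stage testable without downloads.

## Worked example

```python
from pseudospace import (
    PseudoSpaceModel, SimConfig, simulate_paired, pairwise_distance_pcc,
    adjusted_rand_index,
)

pair = simulate_paired(SimConfig(
    n_genes=2000, n_sc=800, n_st=800, n_pops=5,
    n_spatial_subclusters=2, seed=3,
))
results = PseudoSpaceModel(pair.sc, pair.st, seed=3).fit()
print(results.summary())

pcc = pairwise_distance_pcc(pair.truth_coords_sc,
                            results.pseudo_space.coords)
clusters = results.cluster(target_k=len(set(pair.sc.labels)))
ari = adjusted_rand_index(pair.sc.labels, clusters.labels)
print(f"pairwise-distance PCC = {pcc:.3f}, clustering ARI = {ari:.3f}")
```

Output:

```
Pseudo-space reconstruction results
================================================
SC cells                                     800
ST observations                              800
genes used                                  2000
latent dimension (m)                          50
kernel                                    linear
MMD before (tr KL)                         29.67
MMD after embedding                   1.7008e-13
final training loss                   0.00282872
================================================
pairwise-distance PCC = 0.881, clustering ARI = 0.917
```

`MMD before` is the squared maximum mean discrepancy between the raw SC and
ST profiles — the batch effect the embedding removes (`MMD after` is the
same quantity in the shared latent space, effectively zero). The
pairwise-distance PCC of 0.881 says the reconstructed pseudo-space largely
preserves the true cell-to-cell geometry (the two near-identical
subclusters are placed with more error than the major populations, which
is what pulls it below the no-subcluster regime's typical >0.9); the ARI
of 0.917 scores the space-informed partition against the generating
labels, including those two subclusters that differ from their parent
populations almost only by location.

The same workflow is available from the shell:

```bash
pseudospace simulate --out-dir sim/ --n-genes 2000 --seed 1
pseudospace run --config run.cfg       # flat key = value file
```

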