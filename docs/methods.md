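# Methods

## Model

The package integrates two spatial omics modalities measured on the same
tissue slice — RNA counts paired with ADT protein tags or with ATAC peak
counts — into a single per-spot embedding used for spatial domain
detection and denoising.

**Spatial graph.** Spots are nodes; each spot selects its `r` nearest
neighbors by Euclidean distance on the shared coordinates (default `r = 3`).
The directed selection is symmetrized by union, so an edge exists if either
endpoint chose the other and degrees may exceed `r`. Both modalities share
the same graph; only node features differ. Message passing uses the
symmetric normalization `D^{-1/2} (A + I) D^{-1/2}`.

**Encoders.** Per modality, a two-layer graph-convolutional encoder
(ReLU after each layer, input dropout `p = 0.15` during training) maps the
reduced feature matrix `X_j` (N × d_j) to a latent matrix `Z_j`
(N × latent_dim). Defaults: hidden 256, latent 64 — the reduced inputs are
50-dimensional, so a wider hidden layer costs little and the latent width
matches common practice for spot embeddings; both are configuration
parameters.

**Contrastive objective.** Following the deep-graph-infomax recipe, a
corrupted view shares the graph topology but row-permutes the features
(permutation redrawn each epoch). The local context of spot *i* is the
sigmoid of the mean of its neighbors' embeddings; a bilinear discriminator
`σ(zᵀ W l)` scores spot/context pairs. The loss is binary cross entropy
pushing true pairs toward 1 and corrupted pairs toward 0, averaged over
spots, plus the mirrored term computed from the corrupted view; with an
uninformative discriminator each modality's loss equals exactly `2 ln 2`.
The loss is computed in log-sigmoid form so saturated scores cannot
produce non-finite values.

**Attention fusion.** A scorer shared by both modalities maps each
per-spot latent vector through `tanh(W_v z + b_v)` and a linear read-out to
one scalar per modality; a per-spot softmax turns the two scalars into
weights `α_i` summing to 1, and the fused embedding is the convex
combination `Z_i = α_i1 z_i1 + α_i2 z_i2`. The attention hidden width
defaults to 32.

**Decoders and losses.** Symmetric two-layer GCN decoders project the
fused embedding back to each modality's reduced feature space. The total
loss is

```
L = γ1 L_contrast,1 + γ2 L_contrast,2
  + λ1 mean_i ||x_1i − y_1i||² + λ2 mean_i ||x_2i − y_2i||²
  + μ (1 − mean_i cos(z_1i, z_2i))
```

with default weights `[γ1, γ2, λ1, λ2, μ] = [1, 1, 10, 10, 5]`
(the simulated-data preset). Presets for the real-data platforms
(MISAR-seq, spatial ATAC–RNA-seq, Stereo-CITE-seq) carry their published
learning rates, epochs, neighbor counts and loss weights.

The cosine correspondence term is computed per spot and averaged; the
flattened-matrix alternative collapses to a single global scalar and
cannot align individual spots, so the per-spot form is used. Rows with
zero norm contribute cosine 0 via an epsilon-regularized denominator.

**Optimization.** Full-batch Adam (default moments, no weight decay),
learning rate 0.001, 1000 epochs for simulated data. The optimizer is a
deliberate choice — the training recipe leaves it open. All randomness
(initialization, dropout, corruption permutations) flows from one seed;
two runs with the same seed are bitwise identical. Training runs in
float32 for speed; the final evaluation pass (embeddings, attention
weights, decodings) is recomputed in float64.

The network and its gradients are implemented on a compact reverse-mode
automatic differentiation engine (`spami._tensor`) covering exactly the
operations the model needs; gradients are validated against central
finite differences in the test suite.

## Preprocessing

- RNA: drop genes detected in fewer than 10 spots, depth-normalize each
  spot to the median total count, `log1p`, select up to 3000 highly
  variable genes (dispersion criterion), PCA to 50 components. Loadings
  and centering are stored so decoded embeddings can be back-projected to
  gene space.
- ADT: centered log-ratio per spot with pseudocount 1 (row margin, the
  common convention for antibody panels); no inverse to raw counts is
  defined.
- ATAC: drop peaks active in fewer than 0.5% of spots, TF-IDF weighting
  `log1p(TF · IDF · 1e4)` with `IDF = N / peak frequency`, truncated SVD to
  50 components. The depth-correlated first component is retained.
- Dimension matching: when requested (low-plex protein panels), the
  higher-dimensional matrix is re-reduced to the smaller width.
- SVD/PCA component signs are fixed by forcing each component's
  largest-magnitude loading positive, for reproducibility.

HVG count, normalization target and TF-IDF variant are not pinned by the
training recipe; all three are exposed in the configuration.

## Synthetic data generator

The generator emulates the benchmark design used to validate the method:
four spatially smooth factors plus background — five classes — on a 2D
grid, RNA ~ zero-inflated negative binomial, ADT ~ negative binomial,
ATAC ~ zero-inflated Poisson, with a ladder of additive Gaussian noise.

- **Factor fields.** Isotropic Gaussian kernels at the four grid-quadrant
  centers, `activity = exp(−d²/2b²)`, bandwidth defaulting to
  `min(grid)/6` so blob-to-grid geometry is constant across grid sizes.
  A spot is background when every activity falls below 0.35, else labeled
  by the argmax factor. The original benchmark extracted factors with a
  spatial factor model fitted to data; explicit kernels play the same role
  (smooth labeled domains) while being fully specified and seedable.
- **Count means.** Features are assigned to factors round-robin with
  per-feature loadings `U(1, 2)` plus baseline 0.2, scaled by the
  distribution's mean scale (default 5 for RNA/ADT, 3 for ATAC). The
  kernel field is squashed through a logistic centered at the background
  threshold (width 0.005) before entering the mean, so classes behave as
  discrete cell types: expression plateaus inside a domain and sits at
  baseline outside, with a sub-spot-width smooth transition. Without this
  the mean decays continuously through the label threshold and a wide ring
  of boundary spots is unassignable by any method, which contradicts the
  benchmark's premise of five distinct cell types.
- **Count models.** ZINB (scale 5, θ = 2, π = 0.3), NB (scale 5, θ = 2),
  ZIP (rate scale 3, π = 0.5) — dispersion and sparsity levels typical of
  spot-level RNA/ADT/ATAC data.
- **Noise.** Additive i.i.d. Gaussian noise on the count matrices, clipped
  at zero so log/CLR transforms remain valid; the default ladder is
  sd ∈ {0, 0.5, 1, 1.5, 2}.

What the generator does **not** emulate: batch effects, doublets,
segmentation errors, spatially varying depth, irregular spot geometry, or
realistic gene–gene correlation beyond the shared factors. Passing the
benchmark therefore shows the pipeline recovers planted smooth domains
from overdispersed sparse counts — not that it handles every artifact of
real slices.

## Problem sizes used by the test suite

The replicated benchmark tests train the complete model: domain recovery
and the ablation comparison run on the default 30×30 grid (900 spots,
1000 epochs, three seeds per variant); the noise-ladder sweep runs on a
20×20 grid with the same geometry (bandwidth scales with the grid), three
seeds per noise level. These sizes keep the full suite to roughly a
quarter hour on one CPU while preserving the benchmark's structure.

## Numerical choices and degenerate inputs

- Distance ties in graph construction break by ascending spot index;
  duplicate coordinates are allowed.
- Corruption permutations of the two modalities are drawn independently.
- An isolated spot's local context falls back to `sigmoid(z_i)` (cannot
  occur after symmetrized kNN construction).
- Constant input to Moran's I raises (the statistic is undefined);
  weights are row-normalized and cluster assessment uses one-hot
  indicator columns.
- Leiden clustering defaults to resolution 1.0; when a target cluster
  count is given the resolution is bisected (bracket expansion then 25
  iterations), returning the nearest achievable count if exact matching
  fails.
- Non-finite training loss aborts with the epoch index and per-component
  values.

## Known limitations

- Exactly two modalities; no graph-attention encoders or variational
  variants.
- Full-batch training assumes the slice fits in memory (fine up to ~10k
  spots on one CPU).
- CLR and LSI modalities are denoised in their normalized/reduced space
  only — no inverse to raw counts exists.
- The prior-information extension (external reference encoder with mutual
  nearest-neighbor alignment) and regulatory-link inference are out of
  scope.
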