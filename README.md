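# spami

Spatial multi-omics integration for paired measurements on the same tissue
slice. Given two per-spot feature matrices — RNA counts with ADT protein
tags, or RNA with ATAC peak counts — and their shared 2D coordinates,
`spami` learns one embedding per spot that fuses both modalities with the
spatial neighborhood structure, then uses it for spatial domain detection
and denoising.

The model encodes each modality with a two-layer graph-convolutional
network over the shared k-nearest-neighbor spatial graph, sharpens each
embedding with a deep-graph-infomax-style contrastive objective (true
spot/neighborhood pairs vs pairs from a feature-shuffled graph), aligns the
two embeddings with a per-spot cosine correspondence term, and fuses them
through a learned per-spot attention softmax:

```
α_i = softmax(w_uᵀ tanh(W_v z_im + b_v) + b_u)       m = 1, 2
Z_i = α_i1 z_i1 + α_i2 z_i2
L   = γ1 L_contrast,1 + γ2 L_contrast,2 + λ1 L_rec,1 + λ2 L_rec,2
      + μ (1 − mean_i cos(z_1i, z_2i))
```

Defaults (`[γ1, γ2, λ1, λ2, μ] = [1, 1, 10, 10, 5]`, r = 3 neighbors,
dropout 0.15, Adam at 0.001 for 1000 epochs) are the simulated-data
preset; presets for MISAR-seq, spatial ATAC–RNA-seq and Stereo-CITE-seq
platforms are included. A seedable simulator generates paired datasets
with known domain labels (four Gaussian-kernel factors plus background on
a grid; ZINB / NB / ZIP counts; a Gaussian-noise ladder), so the whole
pipeline is testable offline. See `docs/methods.md` for the full model
description and design rationale.

Intended users: computational biologists analyzing spatial
epigenome–transcriptome or transcriptome–proteome slices, and method
developers who need a reproducible, CPU-only baseline with a ground-truth
simulator.

## Worked example

```python
import numpy as np
from spami import (SpaMI, SimulationConfig, simulate_pair, SpatialOmicsPair,
                   cluster_leiden, evaluate_clustering)
from spami.pipeline import _preprocess_pair

pair = simulate_pair(SimulationConfig(noise_sd=0.5, seed=1))  # 30x30 grid
fm1, fm2 = _preprocess_pair(pair, {})       # RNA -> PCA-50, ADT -> CLR
proc = SpatialOmicsPair(X1=fm1.values, X2=fm2.values,
                        coords=pair.coords, labels=pair.labels)

model = SpaMI(random_state=1).fit(proc)     # ~1 min on one CPU
res = cluster_leiden(model.embedding_, target_n_clusters=5, seed=1)
rep = evaluate_clustering(res.labels, pair.labels)
print(f"clusters={res.n_clusters}  ARI={rep.ari:.3f}")
print("mean attention on RNA:", model.attention_weights_[:, 0].mean().round(3))
```

Output:

```
clusters=5  ARI=0.919
mean attention on RNA: 0.89
```

The five clusters recover the four planted factor domains and the
background (adjusted Rand index 0.919 against the ground-truth labels),
and the attention weights show the model leaning on the RNA modality,
which carries more features in this simulation. `model.loss_history_`
holds the per-epoch contrastive, reconstruction and correspondence terms;
`spami.downstream.denoise` maps decoded embeddings back to gene space.

The same pipeline is available from the shell:

```bash
spami simulate --pair rna_adt --grid 30x30 --noise-sd 0.5 --seed 1 --out sim.h5ad
spami train --in sim.h5ad --out run/
spami cluster --embeddings run/embeddings.npz --n-clusters 5 --seed 1 --out run/clusters.tsv
spami evaluate --clusters run/clusters.tsv --dataset run/dataset.h5ad --out run/metrics.json
```

or end-to-end via `spami run --config cfg.yaml` (every run directory gets
a `manifest.json` with the config snapshot, seed and per-stage timings).

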