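# h2a — cell-type abundance from histology

`h2a` predicts fine-grained cell-type abundance for every spot of a
spatial-transcriptomics slide directly from the H&E image, and carries the
predictions through the downstream analyses that make them useful:
cell-cell colocalization maps, super-resolved abundance grids, and
survival-risk modeling. It is aimed at computational pathology and spatial
biology groups who have deconvolution-derived abundance labels (e.g. from
Cell2location) for some slides and want image-only predictions — plus the
statistics around them — for many more.

## The model

A slide becomes a spatial graph G = {V, E}: spots are nodes at their pixel
coordinates, each connected to its k nearest neighbors (k = 6 for Visium
hex arrays, k = 8 for square ST grids). The computational unit is the
k-hop closure B^k of a sampled center set B (k = 2). Per closure:

* a CNN encoder embeds each spot's patch, `I_emb = I(patch)`;
* GATv2 layers aggregate short-range messages along spatial edges,
  `h'_i = σ(Σ_{j∈N_i} α_ij W h_j)` with
  `α_ij = softmax_j(aᵀ LeakyReLU(W [h_i ‖ h_j]))`;
* Transformer layers attend over all nodes as tokens, capturing long-range
  similarity between distant tissue regions;
* features fuse residually, `X_fuse = w_i I_emb + w_g X_GAT + w_t X_Trans`,
  and an MLP head with softplus outputs non-negative abundances
  `Ŷ = MLP(X_fuse)`, trained with MSE against the labels over all nodes
  of the closure.

Inference is a sliding window: every spot centers its own 2-hop subgraph
and keeps only the center prediction. Colocalization uses bivariate
Moran's R under RBF spatial weights; survival uses a discrete-time hazard
model (interval quartiles of uncensored times, sigmoid hazards, censored
log-likelihood with β-weighted uncensored emphasis) evaluated by Harrell's
concordance index, with integrated-gradients attribution of the cell types
driving predicted risk.

Everything runs on a small numpy reverse-mode autodiff core — no GPU or
deep-learning framework required. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

```python
import numpy as np
from h2a.synthetic import SyntheticSlideConfig, generate_synthetic_slide
from h2a.graph import build_knn_graph
from h2a.slide_io import PatchStack
from h2a.train import CellAbundanceRegressor
from h2a.metrics import evaluate_abundance

def slide_inputs(seed):
    s = generate_synthetic_slide(SyntheticSlideConfig(
        n_rows=20, n_cols=20, n_cell_types=8, patch_size_px=32,
        noise_sd=0.05, seed=seed))
    graph = build_knn_graph(s.coords, 6, s.spot_ids)
    return (graph, PatchStack(s.patches, s.spot_ids, 32)), s.abundance

(X1, y1), (X2, y2), (Xh, yh) = (slide_inputs(s) for s in (1, 2, 3))

est = CellAbundanceRegressor(n_cell_types=8, epochs=30, batch_centers=32,
                             learning_rate=3e-3, seed=0)
est.fit([X1, X2], [y1, y2])
pred = est.predict([Xh])[0]
report = evaluate_abundance(pred, yh, [f"celltype_{t:02d}" for t in range(8)])
print(f"mean Pearson {report.mean_pearson:.3f}, "
      f"mean JSD {report.mean_jsd:.3f} bits")
```

Output (about three minutes on one CPU):

```
mean Pearson 0.966, mean JSD 0.055 bits
```

meaning the held-out slide's per-cell-type abundance maps correlate at
0.97 with the ground truth on average, and the predicted spatial
distributions diverge from the true ones by 0.055 bits of a possible 1.

A shell interface covers the same ground:
`h2a crop`, `h2a train`, `h2a predict`, `h2a coloc`, `h2a evaluate`,
`h2a survival fit|km`.

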