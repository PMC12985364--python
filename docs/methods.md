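# Methods

## Overview

`h2a` predicts per-spot cell-type abundance directly from histology image
patches. A whole slide is abstracted as a spatial graph: spots are nodes at
their pixel coordinates, and each node is connected to its k nearest
neighbors by Euclidean distance (k = 6 matches the hexagonal adjacency of
10x Visium arrays; k = 8 a square ST grid). Training and inference never
touch the whole graph at once: the computational unit is the k-hop closure
B^k of a sampled set of center spots B (k = 2 by default).

The model has four stages:

1. **Patch encoder** `I(·)`: maps each spot's RGB patch to an embedding
   `I_emb ∈ R^{d_emb}`. The default `small_cnn` is three stride-2
   convolution blocks (3→16→32→64 channels, 3×3 kernels, ELU) with global
   average pooling and a linear projection; `resnet18_imagenet` reproduces
   the full-scale configuration when torch/torchvision are available, and
   any frozen feature extractor can be attached through the plugin hook.
2. **Short-range message passing**: stacked GATv2 layers on the subgraph's
   spatial edges. The edge score is `e(h_i, h_j) = aᵀ LeakyReLU(W [h_i ‖
   h_j])` with `W = [W_l | W_r]` splitting over the concatenation; scores
   are softmax-normalized over each node's in-neighborhood and the update is
   `h'_i = ELU(Σ_j α_ij W_r h_j)`.
3. **Long-range attention**: standard post-norm Transformer encoder blocks
   treating every node in the batch's closure as a token (no positional
   encoding, so the layer is permutation-equivariant). During training the
   token set spans the whole minibatch of subgraphs, letting distant but
   morphologically similar spots attend to each other.
4. **Fusion and head**: `X_fuse = w_i·I_emb + w_g·X_GAT + w_t·X_Trans`
   (defaults w = 1, a plain residual sum), then a two-layer MLP with a
   final softplus so predicted abundances are non-negative. The loss is the
   MSE over *all* nodes of the closure.

At inference every spot becomes the center of its own 2-hop subgraph and
only the center-node output is kept (sliding window). The Transformer then
attends within the single subgraph of each center, which makes predictions
independent of how centers are chunked into batches; the cross-subgraph
attention seen during training acts as a stochastic regularizer, and at
inference determinism wins.

## Numerical core

All layers run on a small reverse-mode automatic-differentiation engine
over numpy float64 arrays (`h2a._tensor`). Convolution is im2col + matmul;
sparse attention aggregation uses gather/segment-sum primitives whose
adjoints are scatter-adds. Optimization is Adam (β = 0.9/0.999,
ε = 1e-8). Training is bit-reproducible for a fixed seed and platform
because every source of randomness flows through `numpy.random.default_rng`
seeded from the configuration.

Architectural defaults (all configurable): 2 GATv2 layers, 2 Transformer
layers with 4 heads and a feed-forward width of 128, d_emb = 64 for
`small_cnn` (512 for the ResNet-18 configuration), LeakyReLU slope 0.2,
ELU as the aggregation nonlinearity, scaled dot-product attention
(1/√d_head). Nodes with an empty neighborhood (isolated after induced-edge
restriction) pass through as `ELU(W_r h_i)`, since the attention average is
undefined over an empty set. Default optimization is Adam at lr 1e-3; the desk-scale recovery study
uses lr 3e-3 with 32 batch centers (smaller batches mean more optimization
steps per epoch, which matters when the epoch budget is fixed), while
lr 1e-4 is the more conservative choice for the full-scale encoder.

## Synthetic study conditions

The generator (`h2a.synthetic`) produces the structure the method assumes
while remaining learnable in CPU-minutes:

* **Lattices.** Square or hex grids; hex rows are offset by half a spacing
  so the 6 nearest neighbors of an interior spot are exactly the hex ring,
  mirroring Visium geometry.
* **Abundance fields.** Per cell type, white noise on the grid is smoothed
  with a Gaussian kernel (`field_smoothness`, in spot units), rescaled to
  unit variance, rectified at zero and capped at 3.0. Smoothness ≥ 2 spots
  yields strongly positive Moran's I; rectification makes roughly half the
  values exactly zero, which is the sparse regime deconvolution labels
  live in.
* **Patch encoding.** A patch is divided into one horizontal band per cell
  type; within band t, `round(a_t / 3 · band_area)` pixels are painted in
  the type's fixed hue in a fixed pseudo-random scatter order. Abundances
  are quantized to that pixel grid, so the encoding is exactly invertible
  (`decode_patch`) for noise-free patches — giving the test suite a ground
  truth that is reachable in principle with zero error. Gaussian pixel
  noise (`noise_sd`, on the 0–255 scale) is added on top. This deliberately
  is *not* H&E realism: real morphology-to-abundance mappings are noisier
  and non-local, so passing recovery tests here demonstrates that the
  architecture and optimization work, not that histology carries this much
  signal.
* **Survival cohorts.** Features are i.i.d. standard normal; event times
  are exponential with rate `exp(x·w)` (proportional hazards), and a chosen
  fraction of subjects receives an independent Exponential(1) censoring
  time, with censoring recorded only when it precedes the event. Under this
  model both discrete-hazard fitting and concordance recovery are
  well-posed.

## Colocalization statistics

Spatial weights are a Gaussian RBF kernel on spot distances,
`w0_ij = exp(−d_ij²/2l²)`, diagonal zeroed (standard Moran practice),
normalized by `n/Σw0` so the weights sum to exactly n. The default length
scale is 1.2× the modal nearest-neighbor spot distance — about one ring of
neighbors carrying most of the weight. Bivariate Moran's R between two
abundance fields collapses to univariate Moran's I on the diagonal. Two
numerical notes: the denominator is computed as `sqrt(Σx²·Σy²)` in one
square root so closed-form cases come out exact, and |R| ≤ 1 is an
empirical property of lattice-like spot layouts with smooth kernels rather
than a theorem — near-duplicate points with a tiny length scale concentrate
the normalized weights and can push the quadratic form past 1. Constant
abundance columns are excluded from colocalization matrices (with a
warning) rather than failing the slide.

## Evaluation metrics

Per-cell-type Pearson correlation is computed across spots. The
Jensen-Shannon divergence treats each cell type's spot map as a probability
distribution over spots (spot-axis normalization — the per-type scalar the
figures need), and is reported in bits so the bound is 1.

## Survival model

Times are discretized at the quartiles (type-7 linear-interpolation
quantiles) of *uncensored* subjects' times into four intervals; every
subject, censored or not, is labeled by the interval containing its time.
A linear (optionally one-hidden-layer) head maps slide-level features to
four sigmoid hazards; survival is the cumulative product of (1 − hazard)
with f_surv(0) = 1. The loss blends the full censored log-likelihood with
an uncensored-only term via β (default 0.5); interval labels r ∈ {0..3}
map to 1-based hazard indices u = r + 1, and log arguments are clamped at
1e-7. Risk scores are the negative expected discrete survival
(−Σ_r f_surv(r)).

The concordance index counts admissible pairs (the earlier time is an
observed event), score ties as 1/2 (Harrell's convention), and treats
scores as survival-time surrogates — risk scores are negated before the
comparison so that the printed indicator `1(T̂_i < T̂_j)·1(T_i < T_j)`
applies literally. Kaplan-Meier stratification splits at the median risk.
Integrated gradients use the right-Riemann path sum, exact for linear
models and satisfying completeness to O(1/steps) otherwise.

## Preprocessing rules

A pixel is background iff mean(R,G,B) ≥ 220; a patch is discarded only when
*more than* 75% of its pixels are background; a slide with fewer than 100
surviving patches is rejected. Crop windows are half-open,
`[c − ⌊s/2⌋, c − ⌊s/2⌋ + s)`, on 0-based (x = column, y = row) pixel
coordinates, with half-to-even rounding of non-integer centers. Color
normalization matches per-channel mean/SD in log-optical-density space
(Reinhard-style) against a reference patch; it is deterministic,
structure-preserving in the sense of acting only on channel statistics, and
pluggable — zero-variance channels fall back to mean-centering with a
warning.

## Super-resolution

A factor-f densified grid places sub-spot centers at spacing/f over the
bounding region of the original lattice (original coordinates remain
lattice members; the sampling radius shrinks by f while the patch size is
unchanged). `direct_predict` runs frozen sliding-window inference on the
dense graph; `impute_finetune` first fine-tunes all parameters on the
low-resolution (coordinate, label) pairs at a 10× reduced learning rate.
Grid spacing is inferred per axis as the modal gap between distinct sorted
coordinates; scattered (non-lattice) inputs raise an error that suggests an
explicit spacing override. For hex lattices the x-axis inference returns
the half-column spacing (the natural rectangular cover), so originals stay
on the dense lattice for even factors.

## Problem sizes and defaults used by the checks

The end-to-end recovery study trains on two 20×20-spot slides (8 cell
types, 32×32 patches, noise_sd 0.05) for 30 epochs (batch of 32 centers,
2-hop closures, Adam lr 3e-3) and evaluates on a third held-out slide; survival recovery uses n = 500 subjects, 5 features,
‖w‖ = 2 and 30% censoring over 10 seeds, fit for 300 full-batch Adam
iterations at lr 0.05. These sizes were chosen so a single-CPU run
completes in minutes while keeping the estimates stable.

## Known limitations

* The synthetic abundance→pixel code is far easier than real H&E; results
  on it bound optimization correctness, not biological attainability.
* The Transformer's training-time attention spans the sampled minibatch,
  so learned long-range behavior depends mildly on batch composition;
  inference is scoped per-subgraph for determinism.
* |R| ≤ 1 for Moran's R is empirical on realistic layouts (see above).
* The numpy engine is single-threaded apart from BLAS matmuls; it is meant
  for desk-scale experiments, not WSI-scale training.
* `resnet18_imagenet` requires torch at run time; the numpy training core
  does not backpropagate through torch modules, so pretrained encoders are
  practical only as frozen plugin features.
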