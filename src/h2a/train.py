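"""End-to-end training, sliding-window inference, and super-resolution.

Training iterates minibatches of k-hop subgraphs: each epoch permutes the
spots of every slide so each spot is a batch center exactly once, the loss
is the MSE over *all* nodes of each sampled closure, and the encoder, GAT,
Transformer, and head are optimized jointly.  Inference slides a window
over the whole slide: every spot becomes the center of its own k-hop
subgraph and only the center-node prediction is kept.  During inference the
Transformer attends within the single subgraph of each center, so
predictions are independent of batch composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._tensor import Tensor
from .graph import (SlideGraph, build_knn_graph, make_supergrid,
                    sample_subgraph, sample_training_batches)
from .nn import Adam, SGD, GraphTransformer, ModelConfig, mse_loss
from .slide_io import PatchStack, SpotTable, crop_patches

__all__ = [
    "TrainConfig", "SuperResolutionRequest", "train", "predict_slide",
    "super_resolve", "save_checkpoint", "load_checkpoint",
    "CellAbundanceRegressor",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_centers: int = 64
    hops: int = 2
    learning_rate: float = 1e-3
    optimizer: str = "adam"             # "adam" | "sgd"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class SuperResolutionRequest:
    factor: int
    mode: str = "direct_predict"        # "direct_predict" | "impute_finetune"
    low_res_labels: np.ndarray | None = None
    finetune_epochs: int = 5

    def __post_init__(self):
        if self.mode not in ("direct_predict", "impute_finetune"):
            raise ValueError("unknown super-resolution mode")
        if self.mode == "impute_finetune" and self.low_res_labels is None:
            raise ValueError("impute_finetune requires low_res_labels")


def _check_alignment(graph: SlideGraph, patches: PatchStack,
                     labels: np.ndarray | None) -> None:
    if patches.spot_ids != graph.node_ids:
        raise ValueError("patch stack and graph spot ids are misaligned")
    if labels is not None and len(labels) != graph.n_nodes:
        raise ValueError("label rows do not match graph nodes")


def _make_optimizer(cfg: TrainConfig, params):
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.learning_rate)
    return SGD(params, lr=cfg.learning_rate)


def train(model: GraphTransformer,
          slides: list[tuple[SlideGraph, PatchStack, np.ndarray]],
          cfg: TrainConfig,
          optimizer=None) -> list[float]:
    """Train in place; returns the per-epoch mean loss trace."""
    for graph, patches, labels in slides:
        _check_alignment(graph, patches, np.asarray(labels))
    rng = np.random.default_rng(cfg.seed)
    opt = optimizer if optimizer is not None else \
        _make_optimizer(cfg, model.parameters())
    trace: list[float] = []
    for _ in range(cfg.epochs):
        epoch_losses: list[float] = []
        for graph, patches, labels in slides:
            labels = np.asarray(labels, dtype=np.float64)
            for sub in sample_training_batches(graph, cfg.batch_centers,
                                               cfg.hops, rng):
                pred = model(patches.pixels[sub.nodes],
                             sub.local_edge_index())
                loss = mse_loss(pred, labels[sub.nodes])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    return trace


def predict_slide(model: GraphTransformer, graph: SlideGraph,
                  patches: PatchStack, hops: int = 2) -> np.ndarray:
    """Sliding-window inference: every spot is a subgraph center exactly
    once and only its center-node prediction is kept."""
    _check_alignment(graph, patches, None)
    emb = model.encode(patches.pixels).detach()
    out = np.empty((graph.n_nodes, model.config.n_cell_types))
    for center in range(graph.n_nodes):
        sub = sample_subgraph(graph, [center], hops)
        local_emb = Tensor(emb.data[sub.nodes])
        pred = model.forward_from_embeddings(local_emb,
                                             sub.local_edge_index())
        out[center] = pred.data[sub.local_centers()[0]]
    return out


def super_resolve(model: GraphTransformer, slide_image: np.ndarray,
                  coords: np.ndarray, req: SuperResolutionRequest,
                  patch_size: int, k_neighbors: int = 6, hops: int = 2,
                  spot_radius_px: float | None = None,
                  spacing: tuple[float, float] | None = None,
                  finetune_cfg: TrainConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Predict abundances on a ``factor``-densified sub-spot grid.

    Patches keep the training input size (only the sampling radius shrinks).
    ``direct_predict`` runs frozen inference on the dense grid;
    ``impute_finetune`` first fine-tunes on the low-resolution
    (coordinate, label) pairs at a 10x reduced learning rate.
    Returns (dense_coords, dense_abundance).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if spot_radius_px is None:
        spot_radius_px = patch_size / 2.0
    dense_coords, _ = make_supergrid(coords, req.factor, spot_radius_px,
                                     spacing=spacing)
    if req.mode == "impute_finetune":
        labels = np.asarray(req.low_res_labels, dtype=np.float64)
        if len(labels) != len(coords):
            raise ValueError("low-res labels misaligned with coordinates")
        cfg = finetune_cfg or TrainConfig(epochs=req.finetune_epochs,
                                          hops=hops, seed=0)
        cfg.learning_rate = cfg.learning_rate / 10.0
        spots_lo = SpotTable([f"lo_{i}" for i in range(len(coords))],
                             coords[:, 0], coords[:, 1])
        patches_lo = crop_patches(slide_image, spots_lo, patch_size,
                                  pad_edges=True)
        k_lo = min(k_neighbors, len(coords) - 1)
        graph_lo = build_knn_graph(coords, k_lo, spots_lo.spot_ids)
        train(model, [(graph_lo, patches_lo, labels)], cfg)
    spots_hi = SpotTable([f"hi_{i}" for i in range(len(dense_coords))],
                         dense_coords[:, 0], dense_coords[:, 1])
    patches_hi = crop_patches(slide_image, spots_hi, patch_size,
                              pad_edges=True)
    graph_hi = build_knn_graph(dense_coords,
                               min(k_neighbors, len(dense_coords) - 1),
                               spots_hi.spot_ids)
    pred = predict_slide(model, graph_hi, patches_hi, hops=hops)
    return dense_coords, pred


# -- checkpoints ---------------------------------------------------------

def save_checkpoint(model: GraphTransformer, path) -> None:
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(model.config.to_dict(), fh, indent=2)


def load_checkpoint(path) -> GraphTransformer:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        config = ModelConfig.from_dict(json.load(fh))
    model = GraphTransformer(config)
    data = np.load(path.with_suffix(".npz"))
    model.load_state_arrays([data[f"param_{i}"] for i in range(len(data.files))])
    return model


# -- sklearn-style estimator --------------------------------------------

class CellAbundanceRegressor(BaseEstimator, RegressorMixin):
    """Graph-transformer abundance regressor over slides.

    ``X`` is a list of ``(SlideGraph, PatchStack)`` pairs and ``y`` a list
    of aligned (spots x cell-types) abundance arrays; ``predict`` returns
    one abundance array per slide.  Composes with sklearn's
    ``get_params``/``set_params`` conventions; fitted state lives in
    ``model_`` and ``loss_trace_``.
    """

    def __init__(self, n_cell_types: int = 8, d_emb: int = 64,
                 encoder_kind: str = "small_cnn", n_gat_layers: int = 2,
                 n_transformer_layers: int = 2, n_heads: int = 4,
                 epochs: int = 30, batch_centers: int = 64, hops: int = 2,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 seed: int = 0):
        self.n_cell_types = n_cell_types
        self.d_emb = d_emb
        self.encoder_kind = encoder_kind
        self.n_gat_layers = n_gat_layers
        self.n_transformer_layers = n_transformer_layers
        self.n_heads = n_heads
        self.epochs = epochs
        self.batch_centers = batch_centers
        self.hops = hops
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        from .nn.encoders import EncoderSpec
        return ModelConfig(
            n_cell_types=self.n_cell_types,
            encoder=EncoderSpec(kind=self.encoder_kind, d_emb=self.d_emb),
            n_gat_layers=self.n_gat_layers,
            n_transformer_layers=self.n_transformer_layers,
            n_heads=self.n_heads, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs,
                           batch_centers=self.batch_centers, hops=self.hops,
                           learning_rate=self.learning_rate,
                           optimizer=self.optimizer, seed=self.seed)

    def fit(self, X, y):
        slides = [(graph, patches, np.asarray(labels, dtype=np.float64))
                  for (graph, patches), labels in zip(X, y)]
        self.model_ = GraphTransformer(self._model_config())
        self.loss_trace_ = train(self.model_, slides, self._train_config())
        return self

    def predict(self, X):
        return [predict_slide(self.model_, graph, patches, hops=self.hops)
                for graph, patches in X]
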