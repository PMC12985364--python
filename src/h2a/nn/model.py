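"""The graph-transformer abundance model.

Pipeline per subgraph batch: a patch encoder produces one embedding per node
of the k-hop closure; stacked GATv2 layers aggregate short-range messages
along spatial edges; stacked Transformer layers attend over all tokens in
the batch to capture long-range similarity regardless of distance; the three
feature scales are fused by a weighted residual sum

    X_fuse = w_i * I_fuse + w_g * X_GAT + w_t * X_Trans

and an MLP head with a final softplus maps each node to a non-negative
cell-type abundance vector.  Training minimizes MSE over every node of the
closure; inference keeps only center-node rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .._tensor import Tensor
from .encoders import EncoderSpec, make_encoder
from .layers import GATv2Layer, MLP, Module, TransformerLayer


@dataclass
class FusionWeights:
    w_i: float = 1.0
    w_g: float = 1.0
    w_t: float = 1.0

    def validate(self):
        vals = (self.w_i, self.w_g, self.w_t)
        if not all(np.isfinite(vals)):
            raise ValueError("fusion weights must be finite")
        if all(v == 0 for v in vals):
            raise ValueError("at least one fusion weight must be non-zero")


@dataclass
class ModelConfig:
    n_cell_types: int = 8
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    n_gat_layers: int = 2
    n_transformer_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    fusion: FusionWeights = field(default_factory=FusionWeights)
    head_hidden: int = 64
    leaky_slope: float = 0.2
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"].pop("plugin_fn", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = EncoderSpec(**d["encoder"])
        d["fusion"] = FusionWeights(**d["fusion"])
        return cls(**d)


def fuse_and_predict(i_fuse: Tensor, x_gat: Tensor, x_trans: Tensor,
                     weights: FusionWeights, head: MLP) -> Tensor:
    """Weighted residual fusion followed by the non-negative MLP head."""
    weights.validate()
    if not (i_fuse.shape == x_gat.shape == x_trans.shape):
        raise ValueError("fusion inputs must share shape, got "
                         f"{i_fuse.shape}, {x_gat.shape}, {x_trans.shape}")
    x_fuse = weights.w_i * i_fuse + weights.w_g * x_gat + weights.w_t * x_trans
    return head(x_fuse).softplus()


def mse_loss(pred, target) -> Tensor:
    """Mean squared error over all nodes and cell types."""
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    target = np.asarray(target.data if isinstance(target, Tensor) else target,
                        dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if np.isnan(pred.data).any() or np.isnan(target).any():
        raise ValueError("NaN in loss inputs")
    diff = pred - Tensor(target)
    return (diff * diff).mean()


class GraphTransformer(Module):
    def __init__(self, config: ModelConfig):
        config.fusion.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.encoder.d_emb
        self.encoder = make_encoder(config.encoder, rng)
        self.gat_layers = [GATv2Layer(d, d, rng, config.leaky_slope)
                           for _ in range(config.n_gat_layers)]
        self.transformer_layers = [
            TransformerLayer(d, config.n_heads, config.d_ff, rng)
            for _ in range(config.n_transformer_layers)]
        self.head = MLP([d, config.head_hidden, config.n_cell_types], rng)

    # the encoder is per-patch, so embeddings can be cached and re-used for
    # many overlapping subgraphs during sliding-window inference
    def encode(self, patches: np.ndarray) -> Tensor:
        return self.encoder(patches)

    def forward_from_embeddings(self, emb: Tensor,
                                edge_index: np.ndarray) -> Tensor:
        x = emb
        for gat in self.gat_layers:
            x = gat(x, edge_index)
        x_gat = x
        for tr in self.transformer_layers:
            x = tr(x)
        x_trans = x
        return fuse_and_predict(emb, x_gat, x_trans, self.config.fusion,
                                self.head)

    def __call__(self, patches: np.ndarray,
                 edge_index: np.ndarray) -> Tensor:
        return self.forward_from_embeddings(self.encode(patches), edge_index)

    # -- attention audits ------------------------------------------------
    def attention_rowsums(self) -> list[np.ndarray]:
        """Row sums of every attention distribution from the last forward
        pass (GAT per-node coefficient sums and Transformer softmax rows);
        all should equal 1."""
        sums: list[np.ndarray] = []
        for gat in self.gat_layers:
            if gat.last_alpha_ is not None and gat.last_alpha_.size:
                nodes = np.unique(gat.last_dst_)
                acc = np.zeros(gat.last_dst_.max() + 1)
                np.add.at(acc, gat.last_dst_, gat.last_alpha_)
                sums.append(acc[nodes])
        for tr in self.transformer_layers:
            if tr.last_attention_ is not None:
                sums.append(tr.last_attention_.sum(axis=-1).reshape(-1))
        return sums
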