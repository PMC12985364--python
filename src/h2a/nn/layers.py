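"""Network layers: linear/MLP, layer norm, strided conv, GATv2, Transformer."""

from __future__ import annotations

import numpy as np

from .._tensor import Tensor, pad2d, segment_softmax, segment_sum, softmax


class Module:
    """Base class: recursive parameter discovery over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} tensors, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _param(rng: np.random.Generator, *shape, fan_in=None, fan_out=None) -> Tensor:
    """Glorot-uniform initialized trainable tensor."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = _param(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Plain feed-forward stack with ReLU between layers (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return self.gamma * xn + self.beta


class Conv2d(Module):
    """Strided 2-D convolution via im2col; input layout (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        k2 = c_in * kernel * kernel
        self.W = _param(rng, c_out, k2, fan_in=k2, fan_out=c_out)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self._index_cache: dict[tuple, np.ndarray] = {}

    def _im2col_index(self, n, hp, wp):
        # cache only the per-sample (K, L) index: batch sizes vary per
        # subgraph, so keying on n would grow without bound
        key = (hp, wp)
        per_sample = self._index_cache.get(key)
        if per_sample is None:
            k, s = self.kernel, self.stride
            oh = (hp - k) // s + 1
            ow = (wp - k) // s + 1
            c_idx, kh, kw = np.meshgrid(np.arange(self.c_in), np.arange(k),
                                        np.arange(k), indexing="ij")
            base = (c_idx * hp * wp + kh * wp + kw).reshape(-1)    # (K,)
            oy, ox = np.meshgrid(np.arange(oh) * s, np.arange(ow) * s,
                                 indexing="ij")
            offs = (oy * wp + ox).reshape(-1)                      # (L,)
            per_sample = base[:, None] + offs[None, :]             # (K, L)
            self._index_cache[key] = per_sample
        sample_off = (np.arange(n) * self.c_in * hp * wp)[:, None, None]
        return per_sample[None] + sample_off                       # (N, K, L)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        xp = pad2d(x, self.padding)
        hp, wp = h + 2 * self.padding, w + 2 * self.padding
        k, s = self.kernel, self.stride
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        idx = self._im2col_index(n, hp, wp)
        cols = xp.take_flat(idx)                                   # (N, K, L)
        kdim = self.c_in * k * k
        cols2 = cols.transpose(1, 0, 2).reshape(kdim, n * oh * ow)
        out = self.W @ cols2                                       # (O, N*L)
        out = out.reshape(self.c_out, n, oh * ow).transpose(1, 0, 2)
        out = out + self.b.reshape(1, self.c_out, 1)
        return out.reshape(n, self.c_out, oh, ow)


class GATv2Layer(Module):
    """Graph attention (v2 scoring): per-edge score
    ``e(h_i, h_j) = aᵀ LeakyReLU(W [h_i ‖ h_j])``, softmax-normalized over the
    in-neighborhood of each node i, aggregation ``h'_i = σ(Σ_j α_ij W_r h_j)``
    where ``W = [W_l | W_r]`` splits over the concatenation and σ is ELU.

    Nodes with an empty neighborhood pass through as ``σ(W_r h_i)``.
    Attention coefficients of the latest forward pass are kept in
    ``last_alpha_`` / ``last_dst_`` for normalization audits.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2):
        self.Wl = _param(rng, d_in, d_out)
        self.Wr = _param(rng, d_in, d_out)
        self.a = _param(rng, d_out, fan_in=d_out, fan_out=1)
        self.leaky_slope = leaky_slope
        self.last_alpha_: np.ndarray | None = None
        self.last_dst_: np.ndarray | None = None

    def __call__(self, h: Tensor, edge_index: np.ndarray) -> Tensor:
        n = h.shape[0]
        src, dst = np.asarray(edge_index[0]), np.asarray(edge_index[1])
        hl = h @ self.Wl           # target-side transform
        hr = h @ self.Wr           # source-side transform (messages)
        if src.size:
            z = hl.gather(dst) + hr.gather(src)          # W [h_i ‖ h_j]
            e = z.leaky_relu(self.leaky_slope) @ self.a  # (E,)
            alpha = segment_softmax(e, dst, n)
            msg = alpha.reshape(-1, 1) * hr.gather(src)
            agg = segment_sum(msg, dst, n)
            self.last_alpha_ = alpha.data.copy()
            self.last_dst_ = dst.copy()
        else:
            agg = Tensor(np.zeros(hr.shape))
            self.last_alpha_ = np.zeros(0)
            self.last_dst_ = np.zeros(0, dtype=int)
        has_in = np.zeros((n, 1))
        if src.size:
            has_in[np.unique(dst)] = 1.0
        out = agg + Tensor(1.0 - has_in) * hr   # isolated: self-message
        return out.elu()


class TransformerLayer(Module):
    """Post-norm Transformer encoder block: multi-head self-attention with a
    residual + LayerNorm, then a row-wise feed-forward with residual +
    LayerNorm.  No positional encoding — tokens are graph nodes and the layer
    is permutation-equivariant.  Attention uses scaled dot products
    (1/√d_head) with row-wise softmax.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.Wq = _param(rng, d_model, d_model)
        self.Wk = _param(rng, d_model, d_model)
        self.Wv = _param(rng, d_model, d_model)
        self.Wo = _param(rng, d_model, d_model)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.last_attention_: np.ndarray | None = None

    def _multihead(self, x: Tensor) -> Tensor:
        n, d = x.shape
        H, dh = self.n_heads, self.d_head
        q = (x @ self.Wq).reshape(n, H, dh).transpose(1, 0, 2)   # (H, n, dh)
        k = (x @ self.Wk).reshape(n, H, dh).transpose(1, 0, 2)
        v = (x @ self.Wv).reshape(n, H, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))  # (H, n, n)
        attn = softmax(scores, axis=-1)
        self.last_attention_ = attn.data.copy()
        out = attn @ v                                            # (H, n, dh)
        out = out.transpose(1, 0, 2).reshape(n, d)
        return out @ self.Wo

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] == 0:
            raise ValueError("transformer layer received an empty token set")
        z = self.ln1(x + self._multihead(x))
        return self.ln2(z + self.ff2(self.ff1(z).relu()))
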