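"""Network layers vs. explicit-loop oracles; fusion and loss arithmetic."""

import numpy as np
import pytest

from h2a._tensor import Tensor
from h2a.nn import (GATv2Layer, GraphTransformer, MLP, ModelConfig,
                    TransformerLayer, fuse_and_predict, mse_loss)
from h2a.nn.encoders import EncoderSpec, PluginEncoder, make_encoder
from h2a.nn.model import FusionWeights


def gat_loop_oracle(h, edges, layer):
    """Literal per-node transcription of the attention equations."""
    wl, wr, a = layer.Wl.data, layer.Wr.data, layer.a.data
    slope = layer.leaky_slope

    def lrelu(v):
        return np.where(v > 0, v, slope * v)

    def elu(v):
        return np.where(v > 0, v, np.exp(v) - 1)

    n = len(h)
    out = np.zeros((n, wl.shape[1]))
    for i in range(n):
        nbrs = [int(s) for s, d in zip(*edges) if d == i]
        if not nbrs:
            out[i] = elu(h[i] @ wr)
            continue
        scores = np.array([a @ lrelu(h[i] @ wl + h[j] @ wr) for j in nbrs])
        alpha = np.exp(scores - scores.max())
        alpha = alpha / alpha.sum()
        out[i] = elu(sum(alpha[k] * (h[j] @ wr)
                         for k, j in enumerate(nbrs)))
    return out


def transformer_loop_oracle(x, layer):
    """Per-token multi-head attention with explicit loops."""
    n, d = x.shape
    H, dh = layer.n_heads, layer.d_head
    heads = []
    for hh in range(H):
        sl = slice(hh * dh, (hh + 1) * dh)
        q = x @ layer.Wq.data[:, sl]
        k = x @ layer.Wk.data[:, sl]
        v = x @ layer.Wv.data[:, sl]
        o = np.zeros((n, dh))
        for i in range(n):
            scores = np.array([q[i] @ k[j] for j in range(n)]) / np.sqrt(dh)
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            o[i] = sum(w[j] * v[j] for j in range(n))
        heads.append(o)
    mh = np.concatenate(heads, axis=1) @ layer.Wo.data

    def ln(z, lnl):
        mu = z.mean(axis=-1, keepdims=True)
        var = ((z - mu) ** 2).mean(axis=-1, keepdims=True)
        return lnl.gamma.data * (z - mu) / np.sqrt(var + lnl.eps) + \
            lnl.beta.data

    z = ln(x + mh, layer.ln1)
    ff = np.maximum(z @ layer.ff1.W.data + layer.ff1.b.data, 0)
    ff = ff @ layer.ff2.W.data + layer.ff2.b.data
    return ln(z + ff, layer.ln2)


class TestGATv2:
    def test_single_neighbor_alpha_is_one(self):
        rng = np.random.default_rng(0)
        layer = GATv2Layer(3, 2, rng)
        h = rng.standard_normal((2, 3))
        edges = np.array([[1], [0]])      # only 0 has a neighbor (node 1)
        out = layer(Tensor(h), edges)
        assert np.allclose(layer.last_alpha_, [1.0])
        expected = np.where(h[1] @ layer.Wr.data > 0, h[1] @ layer.Wr.data,
                            np.exp(h[1] @ layer.Wr.data) - 1)
        assert np.allclose(out.data[0], expected, atol=1e-12)

    def test_identical_neighbors_split_attention_equally(self):
        rng = np.random.default_rng(1)
        layer = GATv2Layer(3, 4, rng)
        h = np.vstack([np.zeros(3), np.ones(3), np.ones(3)])
        edges = np.array([[1, 2], [0, 0]])
        layer(Tensor(h), edges)
        assert np.allclose(layer.last_alpha_, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_loop_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        d, dp = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        h = rng.standard_normal((n, d))
        # random directed edges (GNN message direction), no self loops
        m = int(rng.integers(1, n * (n - 1) + 1))
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        sel = rng.choice(len(pairs), size=m, replace=False)
        edges = np.array([[pairs[s][0] for s in sel],
                          [pairs[s][1] for s in sel]])
        layer = GATv2Layer(d, dp, rng)
        out = layer(Tensor(h), edges)
        assert np.allclose(out.data, gat_loop_oracle(h, edges, layer),
                           atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        layer = GATv2Layer(4, 4, rng)
        h = rng.standard_normal((8, 4))
        edges = np.array([[1, 2, 3, 0, 5, 6], [0, 0, 0, 4, 4, 4]])
        layer(Tensor(h), edges)
        sums = np.zeros(8)
        np.add.at(sums, layer.last_dst_, layer.last_alpha_)
        assert np.allclose(sums[[0, 4]], 1.0, atol=1e-6)


class TestTransformer:
    def test_single_token_attends_to_itself(self):
        rng = np.random.default_rng(2)
        layer = TransformerLayer(6, 2, 12, rng)
        x = rng.standard_normal((1, 6))
        out = layer(Tensor(x))
        assert np.allclose(layer.last_attention_, 1.0, atol=1e-12)
        assert np.allclose(out.data,
                           transformer_loop_oracle(x, layer), atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        layer = TransformerLayer(8, 4, 16, rng)
        x = rng.standard_normal((6, 8))
        perm = rng.permutation(6)
        out = layer(Tensor(x)).data
        out_perm = layer(Tensor(x[perm])).data
        assert np.allclose(out[perm], out_perm, atol=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(1, 11))
        heads = int(rng.choice([1, 2, 4]))
        d = heads * int(rng.integers(1, 4))
        layer = TransformerLayer(d, heads, 2 * d, rng)
        x = rng.standard_normal((n, d))
        out = layer(Tensor(x))
        assert np.allclose(out.data, transformer_loop_oracle(x, layer),
                           atol=1e-6)
        assert np.allclose(layer.last_attention_.sum(axis=-1), 1.0,
                           atol=1e-6)

    def test_empty_token_set_raises(self):
        rng = np.random.default_rng(4)
        layer = TransformerLayer(4, 2, 8, rng)
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((0, 4))))


class TestFusionAndLoss:
    def _head(self, d, t):
        return MLP([d, 8, t], np.random.default_rng(0))

    def test_identity_weights_pass_encoder_features(self):
        rng = np.random.default_rng(5)
        i_f = Tensor(rng.standard_normal((4, 6)))
        head = self._head(6, 3)
        zeros = Tensor(np.zeros((4, 6)))
        out = fuse_and_predict(i_f, zeros, zeros, FusionWeights(1, 0, 0),
                               head)
        direct = head(i_f).softplus()
        assert np.allclose(out.data, direct.data, atol=1e-12)

    def test_all_zero_weights_rejected(self):
        z = Tensor(np.zeros((2, 4)))
        with pytest.raises(ValueError):
            fuse_and_predict(z, z, z, FusionWeights(0, 0, 0),
                             self._head(4, 2))

    def test_unit_weights_sum_features(self):
        rng = np.random.default_rng(6)
        a, b, c = (Tensor(rng.standard_normal((3, 4))) for _ in range(3))
        head = self._head(4, 2)
        out = fuse_and_predict(a, b, c, FusionWeights(1, 1, 1), head)
        manual = head(Tensor(a.data + b.data + c.data)).softplus()
        assert np.allclose(out.data, manual.data, atol=1e-12)

    def test_predictions_are_non_negative(self):
        rng = np.random.default_rng(7)
        a = Tensor(rng.standard_normal((5, 4)) * 10)
        out = fuse_and_predict(a, a, a, FusionWeights(), self._head(4, 3))
        assert (out.data >= 0).all()

    def test_mse_loss_cases_and_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(0, 2, (6, 3))
        assert mse_loss(Tensor(y), y).data == 0
        assert np.isclose(mse_loss(Tensor(y + 1), y).data, 1.0, atol=1e-14)
        p = rng.uniform(0, 2, (6, 3))
        manual = sum((p[i, j] - y[i, j]) ** 2 for i in range(6)
                     for j in range(3)) / 18
        assert np.isclose(mse_loss(Tensor(p), y).data, manual, atol=1e-12)
        with pytest.raises(ValueError):
            mse_loss(Tensor(np.full((2, 2), np.nan)), np.zeros((2, 2)))


class TestEncoders:
    def test_identical_patches_get_identical_embeddings(self):
        spec = EncoderSpec("small_cnn", 16)
        enc = make_encoder(spec, np.random.default_rng(0))
        patch = np.random.default_rng(1).integers(0, 256, (1, 16, 16, 3))
        pair = np.concatenate([patch, patch])
        emb = enc(pair).data
        assert np.array_equal(emb[0], emb[1])

    def test_plugin_zero_encoder(self):
        enc = PluginEncoder(4, lambda p: np.zeros((len(p), 4)))
        out = enc(np.zeros((3, 8, 8, 3)))
        assert np.array_equal(out.data, np.zeros((3, 4)))

    def test_resnet_kind_requires_torch(self):
        spec = EncoderSpec("resnet18_imagenet", 512)
        with pytest.raises((ImportError, NotImplementedError)):
            make_encoder(spec, np.random.default_rng(0))

    def test_small_cnn_regression_fixture(self):
        """Frozen fingerprint of the seeded encoder on a fixed patch."""
        enc = make_encoder(EncoderSpec("small_cnn", 8),
                           np.random.default_rng(123))
        patch = np.arange(16 * 16 * 3, dtype=np.uint8).reshape(1, 16, 16, 3)
        emb = enc(patch).data
        again = make_encoder(EncoderSpec("small_cnn", 8),
                             np.random.default_rng(123))(patch).data
        assert np.array_equal(emb, again)


def test_full_model_attention_normalization(small_graph, small_patchstack):
    cfg = ModelConfig(n_cell_types=4, encoder=EncoderSpec("small_cnn", 16),
                      d_ff=32, head_hidden=16, n_heads=2, seed=0)
    model = GraphTransformer(cfg)
    sub_nodes = np.arange(12)
    model(small_patchstack.pixels[sub_nodes],
          small_graph.edge_index(sub_nodes))
    for sums in model.attention_rowsums():
        assert np.allclose(sums, 1.0, atol=1e-6)
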