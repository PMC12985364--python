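"""Bivariate Moran's R colocalization and univariate Moran's I.

The spatial weight matrix is a Gaussian RBF kernel on Euclidean spot
distances, ``w0_ij = exp(-d_ij^2 / (2 l^2))``, with the diagonal zeroed and
an element-wise normalization ``w_ij = (n / W) * w0_ij`` where ``W`` is the
sum of the kernel, so that the weights sum to exactly n.  The colocalization
of two abundance fields x and y is

    R = sum_ij w_ij (x_i - xbar)(y_j - ybar)
        / sqrt(sum_i (x_i - xbar)^2) / sqrt(sum_i (y_i - ybar)^2)

which collapses to univariate Moran's I when y = x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpatialWeights", "ColocalizationMatrix", "rbf_spatial_weights",
    "bivariate_moran_R", "univariate_moran_I", "colocalization_matrix",
    "compare_colocalization", "consensus_colocalization",
    "default_length_scale",
]


@dataclass
class SpatialWeights:
    w: np.ndarray
    length_scale: float
    normalized: bool = True

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass
class ColocalizationMatrix:
    cell_type_names: list[str]
    R: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(self.R, index=self.cell_type_names,
                     columns=self.cell_type_names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ColocalizationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(float))


def default_length_scale(coords: np.ndarray) -> float:
    """1.2 x the modal nearest-neighbor spot distance."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    nn = np.empty(n)
    block = 1024
    for s in range(0, n, block):
        e = min(s + block, n)
        d2 = ((coords[s:e, None] - coords[None]) ** 2).sum(-1)
        d2[np.arange(e - s), np.arange(s, e)] = np.inf
        nn[s:e] = np.sqrt(d2.min(axis=1))
    vals, counts = np.unique(np.round(nn, 6), return_counts=True)
    return 1.2 * float(vals[np.argmax(counts)])


def rbf_spatial_weights(coords: np.ndarray,
                        length_scale: float) -> SpatialWeights:
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 spots")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    w0 = np.exp(-d2 / (2.0 * length_scale ** 2))
    np.fill_diagonal(w0, 0.0)
    total = w0.sum()
    if total == 0:
        raise ValueError("degenerate weights: kernel sums to zero")
    return SpatialWeights(w0 * (n / total), float(length_scale))


def bivariate_moran_R(x: np.ndarray, y: np.ndarray,
                      weights: SpatialWeights) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = weights.n
    if len(x) != n or len(y) != n:
        raise ValueError("field length must match the weight matrix")
    xc, yc = x - x.mean(), y - y.mean()
    sx2 = (xc ** 2).sum()
    sy2 = (yc ** 2).sum()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("Moran statistic undefined for a constant field")
    return float(xc @ weights.w @ yc / np.sqrt(sx2 * sy2))


def univariate_moran_I(x: np.ndarray, weights: SpatialWeights) -> float:
    """Standard Moran's I; under the n-normalized weights used here it equals
    ``bivariate_moran_R(x, x, weights)``."""
    return bivariate_moran_R(x, x, weights)


def colocalization_matrix(values: np.ndarray, cell_type_names: list[str],
                          weights: SpatialWeights) -> ColocalizationMatrix:
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    sd = values.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    skipped = [cell_type_names[t] for t in np.flatnonzero(sd == 0)]
    if skipped:
        warnings.warn(f"skipping constant cell types: {skipped}")
    names = [cell_type_names[t] for t in usable]
    k = len(usable)
    xc = values[:, usable] - values[:, usable].mean(axis=0)
    norms = np.sqrt((xc ** 2).sum(axis=0))
    cross = xc.T @ weights.w @ xc
    r = cross / np.outer(norms, norms)
    # enforce exact symmetry of the quadratic form on symmetric weights
    r = (r + r.T) / 2.0
    assert r.shape == (k, k)
    return ColocalizationMatrix(names, r)


def compare_colocalization(a: ColocalizationMatrix,
                           b: ColocalizationMatrix) -> tuple[float, float]:
    """Cosine similarity and Pearson correlation of the flattened upper
    triangles (diagonal included) of two colocalization matrices."""
    if a.cell_type_names != b.cell_type_names:
        raise ValueError("cell-type names differ between matrices")
    iu = np.triu_indices(len(a.cell_type_names))
    va, vb = a.R[iu], b.R[iu]
    cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    pearson = float(np.corrcoef(va, vb)[0, 1])
    return cos, pearson


def consensus_colocalization(per_slide: list[ColocalizationMatrix],
                             high_R_threshold: float = 0.20
                             ) -> tuple[ColocalizationMatrix, np.ndarray]:
    """Element-wise mean across slides and the count of slides whose R
    exceeds the threshold in each cell."""
    if not per_slide:
        raise ValueError("need at least one slide")
    names = per_slide[0].cell_type_names
    for m in per_slide[1:]:
        if m.cell_type_names != names:
            raise ValueError("cell-type names differ across slides")
    stack = np.stack([m.R for m in per_slide])
    mean = ColocalizationMatrix(names, stack.mean(axis=0))
    counts = (stack > high_R_threshold).sum(axis=0)
    return mean, counts
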