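"""Evaluation statistics for predicted vs. true abundance maps."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .coloc import SpatialWeights, univariate_moran_I

__all__ = [
    "EvalReport", "per_celltype_pearson", "jensen_shannon_divergence",
    "evaluate_abundance", "moran_vs_performance",
]


@dataclass
class EvalReport:
    cell_type_names: list[str]
    per_type_pearson: np.ndarray       # NaN where undefined (constant column)
    per_type_jsd: np.ndarray           # bits
    mean_pearson: float
    mean_jsd: float
    jsd_unit: str = "bits"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_type": self.cell_type_names,
            "pearson": self.per_type_pearson,
            "jsd_bits": self.per_type_jsd,
        })

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean_pearson": self.mean_pearson,
                       "mean_jsd": self.mean_jsd,
                       "jsd_unit": self.jsd_unit}, fh, indent=2)


def per_celltype_pearson(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pearson correlation across spots, one value per cell type; NaN (with
    a warning) for cell types whose prediction or truth is constant."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    out = np.empty(pred.shape[1])
    for t in range(pred.shape[1]):
        p, q = pred[:, t], truth[:, t]
        if p.std() == 0 or q.std() == 0:
            warnings.warn(f"cell type {t} constant; Pearson undefined")
            out[t] = np.nan
        else:
            out[t] = np.corrcoef(p, q)[0, 1]
    return out


def jensen_shannon_divergence(p_map: np.ndarray, q_map: np.ndarray) -> float:
    """JSD between the two maps viewed as probability distributions over
    spots (each map normalized to sum 1), in bits; bounded by 1."""
    p = np.asarray(p_map, dtype=np.float64)
    q = np.asarray(q_map, dtype=np.float64)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("maps must be non-negative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("maps must have positive total mass")
    return float(jensenshannon(p, q, base=2) ** 2)


def evaluate_abundance(pred: np.ndarray, truth: np.ndarray,
                       cell_type_names: list[str]) -> EvalReport:
    pearson = per_celltype_pearson(pred, truth)
    jsd = np.array([jensen_shannon_divergence(pred[:, t], truth[:, t])
                    if pred[:, t].sum() > 0 and truth[:, t].sum() > 0
                    else np.nan
                    for t in range(pred.shape[1])])
    return EvalReport(list(cell_type_names), pearson, jsd,
                      float(np.nanmean(pearson)), float(np.nanmean(jsd)))


def moran_vs_performance(truth: np.ndarray, pearson: np.ndarray,
                         weights: SpatialWeights,
                         cell_type_names: list[str] | None = None
                         ) -> tuple[pd.DataFrame, float]:
    """Univariate Moran's I of each true abundance column paired with the
    per-type prediction Pearson, plus the correlation between the two.

    Spatially coherent cell types tend to be predicted better from
    morphology; the returned correlation quantifies that trend.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pearson = np.asarray(pearson, dtype=np.float64)
    if cell_type_names is None:
        cell_type_names = [str(t) for t in range(truth.shape[1])]
    rows = []
    for t in range(truth.shape[1]):
        if truth[:, t].std() == 0 or not np.isfinite(pearson[t]):
            continue
        rows.append((cell_type_names[t],
                     univariate_moran_I(truth[:, t], weights), pearson[t]))
    if len(rows) < 3:
        raise ValueError("need at least 3 usable cell types")
    table = pd.DataFrame(rows, columns=["cell_type", "moran_I", "pearson"])
    if table["pearson"].std() == 0 or table["moran_I"].std() == 0:
        warnings.warn("correlation undefined (constant column); returning NaN")
        corr = float("nan")
    else:
        corr = float(np.corrcoef(table["moran_I"], table["pearson"])[0, 1])
    return table, corr
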