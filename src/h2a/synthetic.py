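"""Synthetic slides, abundance labels, and survival cohorts.

The generator produces the statistical structure the abundance model
assumes, at desk scale:

* spots on a square or hex lattice (hex rows offset by half a spacing so
  6-NN reproduces Visium adjacency; square pairs with 8-NN);
* per-cell-type latent abundance fields made by Gaussian-smoothing white
  noise over the lattice and rectifying to non-negative, so fields are
  spatially autocorrelated (positive Moran's I for smoothness >= 2 spots);
* one RGB patch per spot whose pixel content deterministically encodes the
  spot's abundance vector: the patch is split into one horizontal band per
  cell type, and within band t a number of pixels proportional to the
  abundance of type t is painted in that type's fixed hue, in a fixed
  pseudo-random scatter order.  Abundances are quantized to the band's
  pixel grid, so with ``noise_sd=0`` the abundance vector is exactly
  recoverable from the patch (see :func:`decode_patch`);
* survival cohorts with exponential proportional-hazards event times whose
  log-rate is a linear function of i.i.d. standard-normal features, plus
  independent Exponential(1) censoring for a chosen fraction of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SyntheticSlideConfig", "SyntheticSlide", "generate_synthetic_slide",
    "decode_patch", "cell_type_colors", "render_slide_image", "render_patch",
    "SurvivalCohort",
    "generate_survival_cohort", "write_slide", "ABUNDANCE_CAP",
]

# latent abundances live in [0, ABUNDANCE_CAP]; the cap maps to a fully
# painted band in the patch encoding
ABUNDANCE_CAP = 3.0


@dataclass
class SyntheticSlideConfig:
    n_rows: int = 20
    n_cols: int = 20
    grid: str = "hex"                   # "square" | "hex"
    spot_spacing_px: float = 32.0
    patch_size_px: int = 32
    n_cell_types: int = 8
    field_smoothness: float = 2.0       # Gaussian sigma, in spot units
    noise_sd: float = 0.05              # pixel noise, on the 0-255 scale
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")
        if self.patch_size_px < 8:
            raise ValueError("patch_size_px must be >= 8")
        if self.spot_spacing_px <= 0:
            raise ValueError("spot_spacing_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.field_smoothness <= 0:
            raise ValueError("field_smoothness must be positive")
        if self.grid not in ("square", "hex"):
            raise ValueError("grid must be 'square' or 'hex'")


@dataclass
class SyntheticSlide:
    spot_ids: list[str]
    coords: np.ndarray                  # (n, 2) pixel (x, y)
    patches: np.ndarray                 # (n, p, p, 3) uint8
    abundance: np.ndarray               # (n, T) non-negative
    cell_type_names: list[str]
    config: SyntheticSlideConfig
    render_map: str = field(default=(
        "per-type horizontal bands; painted-pixel count = "
        "round(abundance / ABUNDANCE_CAP * band_area); fixed hue per type"))


def cell_type_colors(n_types: int) -> np.ndarray:
    """Fixed saturated RGB color per cell type (uint8), evenly spaced hues."""
    import matplotlib.colors as mcolors
    hues = np.arange(n_types) / n_types
    hsv = np.stack([hues, np.ones(n_types), 0.9 * np.ones(n_types)], axis=1)
    return (mcolors.hsv_to_rgb(hsv) * 255).round().astype(np.uint8)


def _grid_coords(cfg: SyntheticSlideConfig) -> np.ndarray:
    r, c = np.meshgrid(np.arange(cfg.n_rows), np.arange(cfg.n_cols),
                       indexing="ij")
    x = c.astype(float) * cfg.spot_spacing_px
    if cfg.grid == "hex":
        x = x + (r % 2) * cfg.spot_spacing_px / 2.0
        y = r.astype(float) * cfg.spot_spacing_px * np.sqrt(3) / 2.0
    else:
        y = r.astype(float) * cfg.spot_spacing_px
    # offset so every patch window stays inside a non-negative canvas
    half = cfg.patch_size_px / 2.0
    return np.column_stack([x.ravel() + half, y.ravel() + half])


def _latent_fields(cfg: SyntheticSlideConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_spots, T) rectified smoothed-noise fields, quantized to the patch
    encoding grid."""
    band_rows = cfg.patch_size_px // cfg.n_cell_types
    if band_rows < 1:
        raise ValueError("patch too small for the number of cell types")
    q = band_rows * cfg.patch_size_px          # pixels per band
    fields = np.empty((cfg.n_rows * cfg.n_cols, cfg.n_cell_types))
    for t in range(cfg.n_cell_types):
        z = rng.standard_normal((cfg.n_rows, cfg.n_cols))
        sm = ndimage.gaussian_filter(z, sigma=cfg.field_smoothness,
                                     mode="reflect")
        sd = sm.std()
        if sd > 0:
            sm = sm / sd
        a = np.maximum(sm, 0.0)                # rectify to non-negative
        a = np.minimum(a, ABUNDANCE_CAP)
        m = np.round(a / ABUNDANCE_CAP * q)    # quantize to band pixel grid
        fields[:, t] = (m / q * ABUNDANCE_CAP).ravel()
    return fields


def _paint_order(patch_size: int, band_rows: int, t: int) -> np.ndarray:
    """Fixed pseudo-random order of the band's pixels (depends only on the
    cell-type index, so a patch is a pure function of its abundance vector)."""
    rng = np.random.default_rng(1000 + t)
    return rng.permutation(band_rows * patch_size)


def _render_patch(abund: np.ndarray, cfg: SyntheticSlideConfig,
                  colors: np.ndarray, orders: list[np.ndarray]) -> np.ndarray:
    p = cfg.patch_size_px
    band_rows = p // cfg.n_cell_types
    q = band_rows * p
    patch = np.full((p, p, 3), 255, dtype=np.float64)
    for t in range(cfg.n_cell_types):
        m = int(round(abund[t] / ABUNDANCE_CAP * q))
        if m == 0:
            continue
        flat = orders[t][:m]
        rows = t * band_rows + flat // p
        cols = flat % p
        patch[rows, cols] = colors[t]
    return patch


def render_patch(abund: np.ndarray, config: SyntheticSlideConfig) -> np.ndarray:
    """Noise-free patch for a given abundance vector (the deterministic
    abundance -> pixel encoding)."""
    colors = cell_type_colors(config.n_cell_types)
    band_rows = config.patch_size_px // config.n_cell_types
    orders = [_paint_order(config.patch_size_px, band_rows, t)
              for t in range(config.n_cell_types)]
    return _render_patch(np.asarray(abund, float), config, colors,
                         orders).astype(np.uint8)


def generate_synthetic_slide(config: SyntheticSlideConfig) -> SyntheticSlide:
    rng = np.random.default_rng(config.seed)
    coords = _grid_coords(config)
    abundance = _latent_fields(config, rng)
    colors = cell_type_colors(config.n_cell_types)
    band_rows = config.patch_size_px // config.n_cell_types
    orders = [_paint_order(config.patch_size_px, band_rows, t)
              for t in range(config.n_cell_types)]
    n = len(coords)
    p = config.patch_size_px
    patches = np.empty((n, p, p, 3), dtype=np.uint8)
    for i in range(n):
        img = _render_patch(abundance[i], config, colors, orders)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        patches[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    ids = [f"spot_{i:05d}" for i in range(n)]
    names = [f"celltype_{t:02d}" for t in range(config.n_cell_types)]
    return SyntheticSlide(ids, coords, patches, abundance, names, config)


def decode_patch(patch: np.ndarray, n_cell_types: int) -> np.ndarray:
    """Invert the band/hue encoding: count painted pixels per band and map
    back to abundance.  Exact for noise-free patches."""
    p = patch.shape[0]
    band_rows = p // n_cell_types
    q = band_rows * p
    colors = cell_type_colors(n_cell_types).astype(int)
    out = np.empty(n_cell_types)
    for t in range(n_cell_types):
        band = patch[t * band_rows:(t + 1) * band_rows].reshape(-1, 3).astype(int)
        painted = (np.abs(band - colors[t]).sum(axis=1) == 0).sum()
        out[t] = painted / q * ABUNDANCE_CAP
    return out


def render_slide_image(slide: SyntheticSlide) -> np.ndarray:
    """Compose the per-spot patches onto one RGB canvas at their centers
    (white background)."""
    p = slide.config.patch_size_px
    half = p // 2
    xmax = int(np.ceil(slide.coords[:, 0].max() + p))
    ymax = int(np.ceil(slide.coords[:, 1].max() + p))
    canvas = np.full((ymax, xmax, 3), 255, dtype=np.uint8)
    for i, (x, y) in enumerate(slide.coords):
        r0 = int(round(y)) - half
        c0 = int(round(x)) - half
        canvas[r0:r0 + p, c0:c0 + p] = slide.patches[i]
    return canvas


def write_slide(slide: SyntheticSlide, out_dir) -> None:
    """One PNG per patch plus spots and abundance CSVs."""
    from PIL import Image
    out = Path(out_dir)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    for sid, patch in zip(slide.spot_ids, slide.patches):
        Image.fromarray(patch).save(out / "patches" / f"{sid}.png")
    pd.DataFrame({"spot_id": slide.spot_ids,
                  "x_px": slide.coords[:, 0],
                  "y_px": slide.coords[:, 1]}).to_csv(
        out / "spots.csv", index=False)
    ab = pd.DataFrame(slide.abundance, columns=slide.cell_type_names)
    ab.insert(0, "spot_id", slide.spot_ids)
    ab.to_csv(out / "abundance.csv", index=False)


# -- survival cohorts ----------------------------------------------------

@dataclass
class SurvivalCohort:
    subject_ids: list[str]
    features: np.ndarray                # (n, k)
    times: np.ndarray                   # continuous, months
    censor: np.ndarray                  # 1 = survives beyond follow-up
    labels: np.ndarray | None = None    # discrete interval labels
    cuts: np.ndarray | None = None

    def to_csv(self, path) -> None:
        k = self.features.shape[1]
        df = pd.DataFrame(self.features,
                          columns=[f"feature_{j + 1}" for j in range(k)])
        df.insert(0, "subject_id", self.subject_ids)
        df["time"] = self.times
        df["censor"] = self.censor
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path)
        feats = [c for c in df.columns if c.startswith("feature_")]
        return cls(df["subject_id"].astype(str).tolist(),
                   df[feats].to_numpy(float),
                   df["time"].to_numpy(float),
                   df["censor"].to_numpy(int))


def generate_survival_cohort(n: int, n_features: int, true_weights,
                             censor_frac: float, seed: int) -> SurvivalCohort:
    """Exponential proportional-hazards cohort: event rate exp(x·w)."""
    true_weights = np.asarray(true_weights, dtype=np.float64)
    if len(true_weights) != n_features:
        raise ValueError("true_weights length must equal n_features")
    if not 0.0 <= censor_frac <= 1.0:
        raise ValueError("censor_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_features))
    rate = np.exp(x @ true_weights)
    event_t = rng.exponential(1.0 / rate)
    censor = np.zeros(n, dtype=int)
    times = event_t.copy()
    n_cens = int(round(censor_frac * n))
    if n_cens:
        idx = rng.choice(n, size=n_cens, replace=False)
        c_t = rng.exponential(1.0, size=n_cens)
        early = c_t < event_t[idx]
        times[idx[early]] = c_t[early]
        censor[idx[early]] = 1
    ids = [f"subject_{i:05d}" for i in range(n)]
    return SurvivalCohort(ids, x, times, censor)
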