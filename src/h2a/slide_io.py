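"""Patch cropping, tissue filtering, color normalization, and table I/O.

Conventions: pixel coordinates are 0-based with x = column and y = row;
crop windows are half-open ``[c - floor(s/2), c - floor(s/2) + s)`` per
axis; non-integer spot centers are rounded half-to-even before cropping.

A pixel counts as background when its mean RGB value is >= 220 (close to
white); a patch is discarded when more than 75% of its pixels are
background; a slide is rejected when fewer than 100 patches survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpotTable", "PatchStack", "read_slide_image", "crop_patches",
    "is_background_pixel", "patch_background_fraction", "keep_patch",
    "filter_slide", "SlideRejected", "normalize_color",
    "read_spot_table", "write_spot_table",
    "read_abundance_csv", "write_abundance_csv",
]

BACKGROUND_MEAN_RGB = 220.0
DEFAULT_MAX_BG_FRAC = 0.75
DEFAULT_MIN_VALID = 100


@dataclass
class SpotTable:
    spot_ids: list[str]
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self):
        self.x_px = np.asarray(self.x_px, dtype=np.float64)
        self.y_px = np.asarray(self.y_px, dtype=np.float64)
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot ids must be unique")
        if not (np.isfinite(self.x_px).all() and np.isfinite(self.y_px).all()):
            raise ValueError("spot coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])

    def __len__(self):
        return len(self.spot_ids)


@dataclass
class PatchStack:
    pixels: np.ndarray                 # (n, s, s, 3), values in [0, 255]
    spot_ids: list[str]
    patch_size: int = 224
    source_slide: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 4 or px.shape[1] != px.shape[2] or px.shape[3] != 3:
            raise ValueError("pixels must be (n, s, s, 3)")
        if px.shape[1] != self.patch_size:
            raise ValueError("patch_size does not match pixel array")
        if len(self.spot_ids) != px.shape[0]:
            raise ValueError("one spot id per patch required")

    def __len__(self):
        return self.pixels.shape[0]


class SlideRejected(Exception):
    """Raised when a slide keeps fewer valid patches than the minimum."""

    def __init__(self, n_valid: int, min_valid: int):
        self.n_valid, self.min_valid = n_valid, min_valid
        super().__init__(
            f"slide rejected: {n_valid} valid patches < minimum {min_valid}")


def read_slide_image(path) -> np.ndarray:
    """PNG/TIFF slide raster as (H, W, 3) uint8."""
    from PIL import Image
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def crop_patches(slide_image: np.ndarray, spots: SpotTable, patch_size: int,
                 pad_edges: bool = False,
                 source_slide: str = "") -> PatchStack:
    """Axis-aligned square patches of side ``patch_size`` centered on spots."""
    img = np.asarray(slide_image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    h, w = img.shape[:2]
    half = patch_size // 2
    cols = np.round(spots.x_px).astype(int)   # numpy rounds half-to-even
    rows = np.round(spots.y_px).astype(int)
    r0, c0 = rows - half, cols - half
    out_of_bounds = (r0 < 0) | (c0 < 0) | (r0 + patch_size > h) | \
        (c0 + patch_size > w)
    if out_of_bounds.any() and not pad_edges:
        bad = [spots.spot_ids[i] for i in np.flatnonzero(out_of_bounds)]
        raise ValueError(
            f"spots too close to the image border for patch_size="
            f"{patch_size}: {bad}")
    if pad_edges and out_of_bounds.any():
        img = np.pad(img, ((patch_size, patch_size),
                           (patch_size, patch_size), (0, 0)),
                     constant_values=255)
        r0, c0 = r0 + patch_size, c0 + patch_size
    patches = np.stack([img[r:r + patch_size, c:c + patch_size]
                        for r, c in zip(r0, c0)])
    return PatchStack(patches, list(spots.spot_ids), patch_size, source_slide)


def is_background_pixel(rgb) -> bool:
    """Background iff mean(R, G, B) >= 220 (a color close to white)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return bool(rgb.mean() >= BACKGROUND_MEAN_RGB)


def patch_background_fraction(patch: np.ndarray) -> float:
    patch = np.asarray(patch, dtype=np.float64)
    bg = patch.mean(axis=-1) >= BACKGROUND_MEAN_RGB
    return float(bg.mean())


def keep_patch(patch: np.ndarray,
               max_bg_frac: float = DEFAULT_MAX_BG_FRAC) -> bool:
    """A patch is discarded only when its background fraction EXCEEDS the
    threshold (a patch at exactly 75% is kept)."""
    return patch_background_fraction(patch) <= max_bg_frac


def filter_slide(patches: PatchStack,
                 max_bg_frac: float = DEFAULT_MAX_BG_FRAC,
                 min_valid: int = DEFAULT_MIN_VALID) -> PatchStack:
    """Drop background patches; reject the slide if too few remain."""
    keep = [i for i in range(len(patches))
            if keep_patch(patches.pixels[i], max_bg_frac)]
    if len(keep) < min_valid:
        raise SlideRejected(len(keep), min_valid)
    return PatchStack(patches.pixels[keep],
                      [patches.spot_ids[i] for i in keep],
                      patches.patch_size, patches.source_slide)


def normalize_color(patch: np.ndarray, reference_patch: np.ndarray
                    ) -> np.ndarray:
    """Reinhard-style normalization: match per-channel mean/SD of the patch
    to the reference in log-optical-density space, then map back to RGB.

    A deterministic, structure-preserving stand-in for stain-separation
    normalizers; the stage is pluggable (any ``(patch, ref) -> patch``
    callable can replace it in the preprocessing chain).
    """
    src = np.asarray(patch, dtype=np.float64)
    ref = np.asarray(reference_patch, dtype=np.float64)
    od_src = -np.log((src + 1.0) / 256.0)
    od_ref = -np.log((ref + 1.0) / 256.0)
    out = np.empty_like(od_src)
    for ch in range(3):
        mu_s, sd_s = od_src[..., ch].mean(), od_src[..., ch].std()
        mu_r, sd_r = od_ref[..., ch].mean(), od_ref[..., ch].std()
        if sd_s == 0:
            warnings.warn(f"channel {ch} has zero variance; centering only")
            out[..., ch] = od_src[..., ch] - mu_s + mu_r
        else:
            out[..., ch] = (od_src[..., ch] - mu_s) / sd_s * sd_r + mu_r
    rgb = np.exp(-out) * 256.0 - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


# -- tables --------------------------------------------------------------

def read_spot_table(path) -> SpotTable:
    df = pd.read_csv(path)
    return SpotTable(df["spot_id"].astype(str).tolist(),
                     df["x_px"].to_numpy(float), df["y_px"].to_numpy(float))


def write_spot_table(table: SpotTable, path) -> None:
    pd.DataFrame({"spot_id": table.spot_ids, "x_px": table.x_px,
                  "y_px": table.y_px}).to_csv(path, index=False)


def read_abundance_csv(path) -> tuple[list[str], list[str], np.ndarray]:
    """Returns (spot_ids, cell_type_names, values)."""
    df = pd.read_csv(path)
    ids = df["spot_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "spot_id"]
    return ids, names, df[names].to_numpy(float)


def write_abundance_csv(spot_ids, cell_type_names, values, path) -> None:
    values = np.asarray(values, dtype=np.float64)
    if np.isnan(values).any():
        raise ValueError("abundance matrix contains NaN")
    if (values < 0).any():
        raise ValueError("abundance values must be non-negative")
    df = pd.DataFrame(values, columns=list(cell_type_names))
    df.insert(0, "spot_id", list(spot_ids))
    df.to_csv(path, index=False, float_format="%.17g")
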