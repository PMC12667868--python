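"""Repair of raw confidence maps into clean binary stomatal masks.

The chain binarises the 0-255 confidence map with Otsu's threshold, then
applies a fixed sequence of defect repairs: remove implausibly large
objects (> 3750 px, larger than any observed stomatal complex or
hydathode), smooth away thin branch-like projections with a
morphological open-then-close, remove implausibly small objects
(< 250 px, smaller than any real stoma) — deliberately *after* the
smoothing step, which can itself shed small fragments — and finally fill
dark holes (pore interiors) inside the kept annotations.

Both size filters are strict inequalities: objects of exactly 250 or
exactly 3750 px are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

from .io import label_objects

__all__ = [
    "PostprocessConfig",
    "otsu_threshold",
    "area_filter",
    "smooth_mask",
    "fill_holes",
    "postprocess_mask",
]


@dataclass(frozen=True)
class PostprocessConfig:
    max_object_px: int = 3750
    min_object_px: int = 250
    smooth_radius: int = 3
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: int = 127

    def __post_init__(self) -> None:
        if self.min_object_px >= self.max_object_px:
            raise ValueError("require min_object_px < max_object_px")
        if self.smooth_radius < 0:
            raise ValueError("smooth_radius must be >= 0")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")


def otsu_threshold(conf: np.ndarray) -> np.ndarray:
    """Binarise a 0-255 confidence map at the Otsu threshold.

    The threshold maximises between-class variance over the 256-bin
    histogram; pixels strictly above it become true.  An all-constant
    raster has no second class: it yields an all-false mask with a
    warning rather than an error.
    """
    conf = np.asarray(conf)
    if conf.size == 0:
        raise ValueError("empty raster")
    if conf.min() == conf.max():
        warnings.warn(
            "constant confidence map: Otsu threshold undefined, returning empty mask",
            stacklevel=2,
        )
        return np.zeros(conf.shape, dtype=bool)
    t = threshold_otsu(conf.astype(np.uint8), nbins=256)
    return conf > t


def area_filter(mask: np.ndarray, min_px: int | None = None, max_px: int | None = None) -> np.ndarray:
    """Drop components strictly smaller than min_px / larger than max_px."""
    labeled = label_objects(mask)
    out = np.asarray(mask).astype(bool).copy()
    for obj in labeled.objects:
        if (max_px is not None and obj.pixel_count > max_px) or (
            min_px is not None and obj.pixel_count < min_px
        ):
            out[labeled.label_map == obj.id] = False
    return out


def smooth_mask(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Morphological opening then closing with a disk; radius 0 is identity.

    Removes protrusions thinner than about twice the radius.  The
    open-then-close composition is idempotent, so smoothing an already
    smoothed mask changes nothing.
    """
    mask = np.asarray(mask).astype(bool)
    if radius == 0:
        return mask.copy()
    se = disk(radius)
    return closing(opening(mask, se), se)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set true every background component not connected to the border."""
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool))


def postprocess_mask(conf: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Full repair chain: threshold, large filter, smooth, small filter, fill."""
    if cfg.threshold_mode == "otsu":
        mask = otsu_threshold(conf)
    else:
        mask = np.asarray(conf) > cfg.fixed_threshold
    mask = area_filter(mask, max_px=cfg.max_object_px)
    mask = smooth_mask(mask, cfg.smooth_radius)
    mask = area_filter(mask, min_px=cfg.min_object_px)
    return fill_holes(mask)
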