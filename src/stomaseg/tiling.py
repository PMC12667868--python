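"""Overlapping 128x128 training tiles and per-epoch augmentation.

Image/mask pairs are cut into square windows whose origins advance by
``window - overlap`` (default 128 - 16 = 112 px); when the last regular
origin does not reach the far edge an extra edge-flush origin is added so
every pixel is covered by at least one tile and no synthetic padding
enters training.

Augmentation follows a fixed recipe: each tile appears as one of the 8
variants of the square-symmetry orbit (1-4 quarter turns, with or
without a vertical-axis flip), then with probability 1/3 the *image*
tile receives a Gaussian blur with kernel size drawn from {3, 5, 7} and
sigma uniform on [0, 3].  Masks are never blurred — labels stay binary.
One variant per tile is resampled each epoch, so the training set
changes between epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "TilingConfig",
    "TilePair",
    "BlurSpec",
    "AugmentationSpec",
    "tile_origins",
    "tile_pairs",
    "geometric_variants",
    "apply_augmentation",
    "build_epoch_dataset",
]

_VALID_KERNELS = (3, 5, 7)


@dataclass(frozen=True)
class TilingConfig:
    window: int = 128
    overlap: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window:
            raise ValueError("require 0 <= overlap < window")

    @property
    def stride(self) -> int:
        return self.window - self.overlap


@dataclass(frozen=True)
class TilePair:
    """A 128x128 (image, mask) window cut at ``origin`` of the source."""

    image_tile: np.ndarray
    mask_tile: np.ndarray
    origin: tuple[int, int]


@dataclass(frozen=True)
class BlurSpec:
    kernel: int
    sigma: float

    def __post_init__(self) -> None:
        if self.kernel not in _VALID_KERNELS:
            raise ValueError(f"kernel must be one of {_VALID_KERNELS}")
        if not 0.0 <= self.sigma <= 3.0:
            raise ValueError("sigma must lie in [0, 3]")


@dataclass(frozen=True)
class AugmentationSpec:
    quarter_turns: int = 4
    vertical_flip: bool = False
    blur: BlurSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quarter_turns not in (1, 2, 3, 4):
            raise ValueError("quarter_turns must be in {1, 2, 3, 4}")


def tile_origins(extent: int, window: int, stride: int) -> list[int]:
    """1D origins: regular stride plus an edge-flush final origin."""
    origins = list(range(0, extent - window + 1, stride))
    if origins[-1] != extent - window:
        origins.append(extent - window)
    return origins


def tile_pairs(image: np.ndarray, mask: np.ndarray, cfg: TilingConfig = TilingConfig()) -> list[TilePair]:
    """Cut an (image, mask) pair into overlapping window tiles."""
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ in shape")
    h, w = image.shape
    win = cfg.window
    if h < win or w < win:
        raise ValueError(f"image {image.shape} smaller than the {win}x{win} window")
    tiles = []
    for r in tile_origins(h, win, cfg.stride):
        for c in tile_origins(w, win, cfg.stride):
            tiles.append(
                TilePair(
                    image_tile=image[r : r + win, c : c + win],
                    mask_tile=mask[r : r + win, c : c + win],
                    origin=(r, c),
                )
            )
    return tiles


def _transform(arr: np.ndarray, quarter_turns: int, vertical_flip: bool) -> np.ndarray:
    out = np.fliplr(arr) if vertical_flip else arr
    return np.rot90(out, k=quarter_turns)  # counter-clockwise


def geometric_variants(tile: TilePair) -> list[TilePair]:
    """The full 8-element orbit: {flip, no flip} x {1..4 quarter turns}.

    Image and mask are transformed identically.  On a tile with no
    symmetry all 8 rasters are distinct.
    """
    if tile.image_tile.shape[0] != tile.image_tile.shape[1]:
        raise ValueError("geometric variants require a square tile")
    out = []
    for flip in (False, True):
        for k in (1, 2, 3, 4):
            out.append(
                TilePair(
                    image_tile=_transform(tile.image_tile, k, flip).copy(),
                    mask_tile=_transform(tile.mask_tile, k, flip).copy(),
                    origin=tile.origin,
                )
            )
    return out


def _gaussian_blur(img: np.ndarray, blur: BlurSpec) -> np.ndarray:
    if blur.sigma <= 0:
        return img.copy()
    radius = (blur.kernel - 1) // 2
    out = ndimage.gaussian_filter(img.astype(np.float64), blur.sigma, radius=radius, mode="nearest")
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def apply_augmentation(tile: TilePair, aug: AugmentationSpec) -> TilePair:
    """Apply one augmentation variant; blur touches the image tile only."""
    img = _transform(tile.image_tile, aug.quarter_turns, aug.vertical_flip)
    msk = _transform(tile.mask_tile, aug.quarter_turns, aug.vertical_flip)
    img = _gaussian_blur(img, aug.blur) if aug.blur is not None else img.copy()
    return TilePair(image_tile=img, mask_tile=msk.copy(), origin=tile.origin)


def sample_augmentation(rng: np.random.Generator) -> AugmentationSpec:
    """Draw one variant: uniform over the 8-orbit, blur with p = 1/3."""
    k = int(rng.integers(1, 5))
    flip = bool(rng.integers(0, 2))
    blur = None
    if rng.random() < 1.0 / 3.0:
        blur = BlurSpec(kernel=int(rng.choice(_VALID_KERNELS)), sigma=float(rng.uniform(0.0, 3.0)))
    return AugmentationSpec(quarter_turns=k, vertical_flip=flip, blur=blur)


def build_epoch_dataset(tiles: list[TilePair], epoch_seed: int) -> list[TilePair]:
    """One freshly drawn augmented variant of every tile, per epoch.

    Fully determined by ``epoch_seed``; the draw is independent per tile
    so the dataset differs between epochs while its size never does.
    """
    if not tiles:
        raise ValueError("tile list is empty")
    rng = np.random.default_rng(epoch_seed)
    return [apply_augmentation(t, sample_augmentation(rng)) for t in tiles]
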