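"""Per-pixel two-class stomatal segmentation with sliding-window inference.

The segmenter is a lightweight learnable model: every pixel of a 128x128
window is described by multiscale rotation-invariant image features
(smoothed intensity, gradient magnitude and Hessian-eigenvalue texture at
sigma 1-16 px) and classified stoma / not-stoma by a small multilayer
perceptron trained with adaptive-moment gradient descent at learning
rate 0.001.  Training follows the per-epoch resampling scheme: the
augmented tile dataset is rebuilt from a fresh seed each epoch, and the
checkpoint with the best validation loss is kept.

Inference slides the training window over the full image with the
training overlap; each window produces a raster of per-pixel log-odds
scores ("logits", unbounded reals), overlapping contributions are
combined by their arithmetic mean in logit space, and the composite is
encoded as a 0-255 confidence map via ``round(255 * sigmoid(logit))`` —
0 meaning ~0% and 255 meaning ~100% confidence that the pixel lies
within a stoma.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass

import joblib
import numpy as np
from skimage.feature import multiscale_basic_features
from sklearn.base import BaseEstimator
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .postprocess import PostprocessConfig, postprocess_mask
from .tiling import TilePair, TilingConfig, build_epoch_dataset, tile_origins, tile_pairs

__all__ = [
    "LogitMap",
    "StomaSegmenter",
    "train",
    "predict_window",
    "composite_windows",
    "logits_to_confidence",
    "predict_image",
]

_P_EPS = 1e-12  # probability clip for the log-odds transform


@dataclass
class LogitMap:
    """Composited per-pixel scores plus how many windows voted per pixel."""

    values: np.ndarray  # float, (-inf, inf) scores
    contribution_count: np.ndarray  # int, windows covering each pixel


def _featurize(tile: np.ndarray, sigma_min: float, sigma_max: float, num_sigma: int) -> np.ndarray:
    return multiscale_basic_features(
        tile.astype(np.float32) / 255.0,
        intensity=True,
        edges=True,
        texture=True,
        sigma_min=sigma_min,
        sigma_max=sigma_max,
        num_sigma=num_sigma,
        workers=1,
    )


def logits_to_confidence(lm: LogitMap | np.ndarray) -> np.ndarray:
    """Encode logits as a 0-255 confidence raster: round(255 * sigmoid)."""
    values = lm.values if isinstance(lm, LogitMap) else np.asarray(lm)
    if not np.all(np.isfinite(values)):
        raise ValueError("logit map contains non-finite values")
    conf = 255.0 / (1.0 + np.exp(-values))
    return np.rint(conf).astype(np.uint8)


def composite_windows(
    window_logits: list[tuple[tuple[int, int], np.ndarray]], extent: tuple[int, int]
) -> LogitMap:
    """Mean-combine overlapping window logits into a whole-image map.

    Every pixel of ``extent`` must be covered by at least one window
    (guaranteed when the windows come from ``tile_pairs``).
    """
    acc = np.zeros(extent, dtype=np.float64)
    cnt = np.zeros(extent, dtype=np.int64)
    for (r, c), raster in window_logits:
        raster = np.asarray(raster)
        hh, ww = raster.shape
        acc[r : r + hh, c : c + ww] += raster
        cnt[r : r + hh, c : c + ww] += 1
    if (cnt == 0).any():
        raise ValueError("windows do not cover the full extent")
    return LogitMap(values=acc / cnt, contribution_count=cnt)


class StomaSegmenter(BaseEstimator):
    """Sliding-window stomatal segmenter (scikit-learn estimator).

    Parameters
    ----------
    window, overlap:
        Tile geometry for training and inference (128 px windows with
        16 px overlap by default, i.e. stride 112).
    learning_rate:
        Step size of the adaptive-moment optimiser.
    epochs:
        Number of passes; the augmented dataset is resampled per epoch.
    pixels_per_tile:
        Pixels sampled per tile per epoch, stratified by class.
    hidden_layer_sizes, alpha:
        Capacity and L2 penalty of the per-pixel MLP.
    sigma_min, sigma_max, num_sigma:
        Scales of the multiscale feature bank.
    random_state:
        Seeds epoch resampling, pixel sampling and weight init.

    Attributes
    ----------
    classifier_ : fitted per-pixel MLP
    training_log_ : list of per-epoch dicts (train/validation loss)
    n_features_ : width of the feature bank
    """

    def __init__(
        self,
        window: int = 128,
        overlap: int = 16,
        learning_rate: float = 0.001,
        epochs: int = 15,
        pixels_per_tile: int = 200,
        hidden_layer_sizes: tuple[int, ...] = (32, 16),
        alpha: float = 1e-4,
        sigma_min: float = 1.0,
        sigma_max: float = 16.0,
        num_sigma: int = 5,
        random_state: int | None = None,
    ) -> None:
        self.window = window
        self.overlap = overlap
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.pixels_per_tile = pixels_per_tile
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.num_sigma = num_sigma
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _tiling(self) -> TilingConfig:
        return TilingConfig(window=self.window, overlap=self.overlap)

    def _featurize(self, tile: np.ndarray) -> np.ndarray:
        return _featurize(tile, self.sigma_min, self.sigma_max, self.num_sigma)

    def _sample_tile_pixels(self, tile: TilePair, rng: np.random.Generator):
        """Class-stratified pixel sample from one (augmented) tile."""
        feats = self._featurize(tile.image_tile).reshape(-1, self.n_features_)
        labels = tile.mask_tile.ravel().astype(np.int8)
        half = self.pixels_per_tile // 2
        idx_parts = []
        for cls, budget in ((1, half), (0, self.pixels_per_tile - half)):
            pool = np.flatnonzero(labels == cls)
            if pool.size:
                idx_parts.append(rng.choice(pool, size=min(budget, pool.size), replace=False))
        idx = np.concatenate(idx_parts)
        return feats[idx], labels[idx]

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (image, mask) pairs, resampling augmentation per epoch.

        Parameters
        ----------
        X, y:
            Lists of same-shape uint8 images and boolean masks.
        X_val, y_val:
            Optional held-out pairs; when given, the per-epoch validation
            loss is logged and the best-validation checkpoint is kept.
        """
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("need equal, nonzero numbers of images and masks")
        for img, msk in zip(X, y):
            msk = np.asarray(msk)
            if np.asarray(img).shape != msk.shape:
                raise ValueError("image/mask shape mismatch")
            if msk.dtype != bool and set(np.unique(msk)) - {0, 1, 255}:
                raise ValueError("masks must be binary")
        cfg = self._tiling()
        tiles = [t for img, msk in zip(X, y) for t in tile_pairs(img, np.asarray(msk).astype(bool), cfg)]
        self.n_features_ = self._featurize(tiles[0].image_tile).shape[-1]

        seed_rng = np.random.default_rng(self.random_state)
        epoch_seeds = seed_rng.integers(0, 2**31 - 1, size=self.epochs)
        clf = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            solver="adam",
            learning_rate_init=self.learning_rate,
            alpha=self.alpha,
            random_state=int(seed_rng.integers(0, 2**31 - 1)),
            max_iter=1,
        )

        # fixed validation sample, featurised once
        val_X = val_y = None
        if X_val is not None and y_val is not None and len(X_val):
            vrng = np.random.default_rng(int(seed_rng.integers(0, 2**31 - 1)))
            parts_X, parts_y = [], []
            for img, msk in zip(X_val, y_val):
                for t in tile_pairs(img, np.asarray(msk).astype(bool), cfg):
                    fx, fy = self._sample_tile_pixels(t, vrng)
                    parts_X.append(fx)
                    parts_y.append(fy)
            val_X = np.concatenate(parts_X)
            val_y = np.concatenate(parts_y)

        self.training_log_ = []
        best = (np.inf, None)
        for epoch, eseed in enumerate(epoch_seeds):
            dataset = build_epoch_dataset(tiles, int(eseed))
            prng = np.random.default_rng(int(eseed) ^ 0x5EED)
            parts_X, parts_y = [], []
            for t in dataset:
                fx, fy = self._sample_tile_pixels(t, prng)
                parts_X.append(fx)
                parts_y.append(fy)
            bx = np.concatenate(parts_X)
            by = np.concatenate(parts_y)
            clf.partial_fit(bx, by, classes=np.array([0, 1]))
            entry = {"epoch": epoch, "train_loss": float(log_loss(by, clf.predict_proba(bx), labels=[0, 1]))}
            if val_X is not None:
                vloss = float(log_loss(val_y, clf.predict_proba(val_X), labels=[0, 1]))
                entry["val_loss"] = vloss
                if vloss < best[0]:
                    best = (vloss, copy.deepcopy(clf))
            self.training_log_.append(entry)
        self.classifier_ = best[1] if best[1] is not None else clf
        return self

    # ------------------------------------------------------------ inference

    def predict_window(self, tile: np.ndarray) -> np.ndarray:
        """Per-pixel logits for one training-sized window."""
        check_is_fitted(self, "classifier_")
        tile = np.asarray(tile)
        if tile.shape != (self.window, self.window):
            raise ValueError(f"tile shape {tile.shape} != ({self.window}, {self.window})")
        feats = self._featurize(tile).reshape(-1, self.n_features_)
        p = self.classifier_.predict_proba(feats)[:, 1]
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        return np.log(p / (1.0 - p)).reshape(self.window, self.window)

    def predict_logits(self, image: np.ndarray) -> LogitMap:
        """Sliding-window inference composited over the full image."""
        check_is_fitted(self, "classifier_")
        image = np.asarray(image)
        h, w = image.shape
        if h < self.window or w < self.window:
            raise ValueError(
                f"image {image.shape} is smaller than the {self.window}px window; "
                "acquire a larger field of view or retrain with a smaller window"
            )
        cfg = self._tiling()
        out = []
        for r in tile_origins(h, cfg.window, cfg.stride):
            for c in tile_origins(w, cfg.window, cfg.stride):
                out.append(((r, c), self.predict_window(image[r : r + cfg.window, c : c + cfg.window])))
        return composite_windows(out, (h, w))

    def predict_confidence(self, image: np.ndarray) -> np.ndarray:
        """0-255 confidence map, same shape as the input image."""
        return logits_to_confidence(self.predict_logits(image))

    def predict(self, image: np.ndarray, postprocess: PostprocessConfig | None = None) -> np.ndarray:
        """Binary stomatal mask: confidence map plus the repair chain."""
        return postprocess_mask(self.predict_confidence(image), postprocess or PostprocessConfig())

    # -------------------------------------------------------- serialization

    def save(self, path: str | os.PathLike) -> None:
        """Write a checkpoint directory (params snapshot + fitted model)."""
        check_is_fitted(self, "classifier_")
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "params.json"), "w") as fh:
            json.dump(self.get_params(), fh, indent=2, default=list)
        joblib.dump(
            {
                "classifier": self.classifier_,
                "n_features": self.n_features_,
                "training_log": self.training_log_,
            },
            os.path.join(path, "model.joblib"),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "StomaSegmenter":
        with open(os.path.join(path, "params.json")) as fh:
            params = json.load(fh)
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        est = cls(**params)
        state = joblib.load(os.path.join(path, "model.joblib"))
        est.classifier_ = state["classifier"]
        est.n_features_ = state["n_features"]
        est.training_log_ = state["training_log"]
        return est


# ------------------------------------------------- thin functional wrappers


def train(scenes, val_scenes=None, **params) -> StomaSegmenter:
    """Fit a :class:`StomaSegmenter` on (image, mask) pairs."""
    X, y = zip(*scenes)
    Xv = yv = None
    if val_scenes:
        Xv, yv = zip(*val_scenes)
    return StomaSegmenter(**params).fit(list(X), list(y), Xv, yv)


def predict_window(model: StomaSegmenter, tile: np.ndarray) -> np.ndarray:
    return model.predict_window(tile)


def predict_image(model: StomaSegmenter, image: np.ndarray) -> np.ndarray:
    """Confidence map for a whole micrograph (the model's primary output)."""
    return model.predict_confidence(image)
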