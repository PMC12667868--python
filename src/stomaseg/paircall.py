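"""PairCaller: single-vs-clustered classification of annotated stomata.

Stomatal clusters — two or more stomata in direct contact, violating the
one-cell-spacing rule — end up as a single mask component.  PairCaller
looks at a fixed 72x72 px crop centred on each component (the size that
captures most single and clustered complexes) and scores it as a single
stoma or a cluster.  Each crop has two planes: the micrograph and the
component's own mask, so the decision rests on the object itself rather
than on neighbours leaking into the field.

Training crops are jittered by a random integer offset per axis so that
the classifier cannot key on exact centring; inference always uses the
centred, un-jittered crop.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import joblib
import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .io import ObjectRecord, label_objects

__all__ = [
    "CropSpec",
    "PairCallRecord",
    "PairCaller",
    "extract_crop",
    "build_crop_dataset",
    "train_pair_classifier",
    "classify_objects",
]

LABELS = ("Single", "Clustered")


@dataclass(frozen=True)
class CropSpec:
    crop_size: int = 72
    jitter_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")


@dataclass(frozen=True)
class PairCallRecord:
    object_id: int
    label: str  # "Single" | "Clustered"
    score: float  # P(cluster), in [0, 1]


def extract_crop(
    image: np.ndarray,
    obj: ObjectRecord,
    spec: CropSpec = CropSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fixed-size window centred on the object centroid, zero-padded.

    When ``rng`` is given the centre receives a uniform integer jitter in
    ``[-jitter_max, +jitter_max]`` per axis (training augmentation);
    without it the crop is exactly centred (inference).  Objects larger
    than the crop are centre-cropped, never rescaled.
    """
    image = np.asarray(image)
    cy, cx = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
    if rng is not None and spec.jitter_max > 0:
        cy += int(rng.integers(-spec.jitter_max, spec.jitter_max + 1))
        cx += int(rng.integers(-spec.jitter_max, spec.jitter_max + 1))
    half = spec.crop_size // 2
    r0, c0 = cy - half, cx - half
    out = np.zeros((spec.crop_size, spec.crop_size), dtype=image.dtype)
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + spec.crop_size, image.shape[0]), min(c0 + spec.crop_size, image.shape[1])
    if re > rs and ce > cs:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return out


def _two_plane_crop(image, label_map, obj, spec, rng=None):
    img_crop = extract_crop(image, obj, spec, rng).astype(np.float32) / 255.0
    msk_crop = extract_crop((label_map == obj.id).astype(np.uint8) * 255, obj, spec, rng)
    return np.stack([img_crop, msk_crop.astype(np.float32) / 255.0], axis=-1)


class PairCaller(BaseEstimator, ClassifierMixin):
    """Two-plane crop classifier for stomatal pairing (sklearn estimator).

    Crops are downsampled to ``downsample`` squared per plane and fed to
    a small MLP; ``predict_proba[:, 1]`` is the cluster probability and
    labels flip to "Clustered" at ``threshold``.
    """

    def __init__(
        self,
        crop_size: int = 72,
        jitter_max: int = 8,
        downsample: int = 24,
        hidden_layer_sizes: tuple[int, ...] = (64,),
        learning_rate: float = 0.001,
        alpha: float = 1e-4,
        max_iter: int = 300,
        threshold: float = 0.5,
        random_state: int | None = None,
    ) -> None:
        self.crop_size = crop_size
        self.jitter_max = jitter_max
        self.downsample = downsample
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.max_iter = max_iter
        self.threshold = threshold
        self.random_state = random_state

    def crop_spec(self) -> CropSpec:
        return CropSpec(crop_size=self.crop_size, jitter_max=self.jitter_max)

    @staticmethod
    def _shape_descriptors(mask_plane: np.ndarray) -> np.ndarray:
        """Whole-object outline descriptors of the crop's mask plane.

        Small touching clusters differ from elongated singles mainly by a
        waist and a second pore slit; solidity, elongation and
        compactness capture the outline part of that signal at full
        resolution, complementing the downsampled pixel planes.
        """
        m = mask_plane > 0.5
        if not m.any():
            return np.zeros(6)
        rp = regionprops(sk_label(m, connectivity=2))[0]
        axis_ratio = rp.axis_major_length / max(rp.axis_minor_length, 1e-6)
        compactness = rp.perimeter**2 / (4.0 * np.pi * rp.area)
        return np.array(
            [m.mean(), rp.eccentricity, axis_ratio / 5.0, rp.solidity, compactness / 5.0, rp.extent]
        )

    def _features(self, crops: np.ndarray) -> np.ndarray:
        d = self.downsample
        out = np.empty((len(crops), 2 * d * d + 6), dtype=np.float64)
        for i, crop in enumerate(crops):
            small = resize(crop, (d, d, 2), order=1, anti_aliasing=True, preserve_range=True)
            # descriptors weighted up so they are not drowned by pixel dims
            out[i] = np.concatenate([small.reshape(-1), 3.0 * self._shape_descriptors(crop[:, :, 1])])
        return out

    def fit(self, X, y):
        """Fit on two-plane crops ``X`` (n, crop, crop, 2) with labels
        ``y`` (0 = single, 1 = cluster); both classes must be present."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4 or X.shape[3] != 2:
            raise ValueError("X must be (n, crop, crop, 2) two-plane crops")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both single and clustered examples")
        self.classifier_ = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            solver="adam",
            learning_rate_init=self.learning_rate,
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        self.classifier_.fit(self._features(X), y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict_proba(self._features(np.asarray(X, dtype=np.float32)))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def classify_objects(self, image: np.ndarray, mask: np.ndarray) -> list[PairCallRecord]:
        """One record per mask component, from centred (un-jittered) crops."""
        check_is_fitted(self, "classifier_")
        labeled = label_objects(mask)
        if not labeled.objects:
            return []
        spec = self.crop_spec()
        crops = np.stack(
            [_two_plane_crop(image, labeled.label_map, o, spec) for o in labeled.objects]
        )
        scores = self.predict_proba(crops)[:, 1]
        return [
            PairCallRecord(
                object_id=o.id,
                label=LABELS[int(s >= self.threshold)],
                score=float(s),
            )
            for o, s in zip(labeled.objects, scores)
        ]

    def save(self, path: str | os.PathLike) -> None:
        check_is_fitted(self, "classifier_")
        joblib.dump({"params": self.get_params(), "classifier": self.classifier_}, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PairCaller":
        state = joblib.load(path)
        params = state["params"]
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        est = cls(**params)
        est.classifier_ = state["classifier"]
        return est


def build_crop_dataset(scenes, spec: CropSpec = CropSpec(), copies_per_object: int = 3, seed: int = 0):
    """Jittered two-plane crops + labels from synthetic scenes.

    Every truth component contributes ``copies_per_object`` independently
    jittered crops labelled by its ``is_cluster`` flag.
    """
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for scene in scenes:
        labeled = label_objects(scene.truth_mask)
        flags = {row.id: row.is_cluster for row in scene.object_table}
        for obj in labeled.objects:
            for _ in range(copies_per_object):
                crops.append(_two_plane_crop(scene.image, labeled.label_map, obj, spec, rng))
                labels.append(int(flags[obj.id]))
    return np.stack(crops), np.array(labels)


def train_pair_classifier(crops, labels, **params) -> PairCaller:
    """Thin wrapper: fit a :class:`PairCaller` on labelled crops."""
    return PairCaller(**params).fit(crops, labels)


def classify_objects(image, mask, model: PairCaller, spec: CropSpec | None = None):
    """Thin wrapper over :meth:`PairCaller.classify_objects`."""
    if spec is not None and spec.crop_size != model.crop_size:
        raise ValueError("spec crop_size differs from the trained model's")
    return model.classify_objects(image, mask)
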