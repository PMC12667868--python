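"""Image and mask I/O in the conventions the rest of the pipeline relies on.

Micrographs are single-channel 2D rasters (TIFF or PNG), annotation masks
are strictly two-valued PNGs whose on-disk pixel values are exactly
``#000000`` and ``#FFFFFF``.  Connected components use 8-connectivity so
that diagonally touching guard-cell junctions are not split.

Conventions: arrays are row-major with origin at the top-left corner,
coordinates are 0-based ``(row, col)``, bounding boxes are half-open
``(row_start, col_start, row_stop, col_stop)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "ObjectRecord",
    "LabeledObjects",
    "read_image",
    "read_mask",
    "write_mask",
    "label_objects",
    "delete_object",
]

# 8-connectivity structuring element for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ObjectRecord:
    """One connected component of a binary mask."""

    id: int
    pixel_count: int
    bounding_box: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    centroid: tuple[float, float]  # (row, col)


@dataclass
class LabeledObjects:
    """Connected components of a mask: a label map plus per-object records.

    ``label_map`` holds 0 for background and consecutive ids 1..N for the
    8-connected components; ``objects[k]`` describes component ``k + 1``.
    """

    label_map: np.ndarray
    objects: list[ObjectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objects)

    def by_id(self, object_id: int) -> ObjectRecord:
        for obj in self.objects:
            if obj.id == object_id:
                return obj
        raise KeyError(f"no object with id {object_id}")


def _as_grayscale(arr: np.ndarray, path: str | os.PathLike) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(
            f"multi-channel input: {path!s} has shape {arr.shape}; "
            "expected a single-channel 2D image (convert upstream)"
        )
    return arr


def read_image(path: str | os.PathLike, normalize: bool = True) -> np.ndarray:
    """Read a grayscale micrograph (TIFF or PNG) as a 2D ``uint8`` array.

    Multi-channel or 3D inputs are rejected rather than silently
    converted.  Inputs deeper than 8 bits are rescaled to 0-255 by
    dividing by the image maximum (``normalize=False`` clips instead).

    Parameters
    ----------
    path:
        Path to a ``.tif``/``.tiff`` or ``.png`` file.
    normalize:
        Rescale >8-bit data by its maximum before casting to uint8.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "P", "1"):
                raise ValueError(
                    f"multi-channel input: {path} has PIL mode {im.mode!r}"
                )
            arr = np.asarray(im.convert("I") if im.mode != "L" else im)
    else:
        raise ValueError(f"unsupported format {ext!r} (expected TIFF or PNG)")
    arr = _as_grayscale(np.asarray(arr), path)
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    if normalize:
        mx = arr.max()
        if mx > 0:
            arr = arr * (255.0 / mx)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_mask(path: str | os.PathLike, strict: bool = True) -> np.ndarray:
    """Read a binary annotation mask from a black/white PNG.

    In strict mode any pixel that is neither 0 nor 255 is an error; in
    lenient mode pixels are binarised at 128 (value >= 128 is true).
    Returns a 2D boolean array.
    """
    path = os.fspath(path)
    with Image.open(path) as im:
        if im.mode == "1":
            im = im.convert("L")
        if im.mode != "L":
            raise ValueError(
                f"mask {path} has PIL mode {im.mode!r}; expected 8-bit grayscale"
            )
        arr = np.asarray(im)
    arr = _as_grayscale(arr, path)
    if strict:
        bad = ~np.isin(arr, (0, 255))
        if bad.any():
            vals = np.unique(arr[bad])[:8]
            raise ValueError(
                f"mask {path} is not strictly binary: found values {vals.tolist()}"
            )
    return arr >= 128


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as a pure black/white (#000000/#FFFFFF) PNG.

    The round trip ``read_mask(write_mask(m)) == m`` is bit-exact.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    out = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(os.fspath(path), format="PNG")


def label_objects(mask: np.ndarray) -> LabeledObjects:
    """Label the 8-connected components of a mask with ids 1..N."""
    mask = np.asarray(mask).astype(bool)
    label_map, n = ndimage.label(mask, structure=_STRUCT8)
    objects: list[ObjectRecord] = []
    if n:
        slices = ndimage.find_objects(label_map)
        centroids = ndimage.center_of_mass(mask, label_map, range(1, n + 1))
        counts = np.bincount(label_map.ravel(), minlength=n + 1)
        for k in range(1, n + 1):
            sl = slices[k - 1]
            objects.append(
                ObjectRecord(
                    id=k,
                    pixel_count=int(counts[k]),
                    bounding_box=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    centroid=(float(centroids[k - 1][0]), float(centroids[k - 1][1])),
                )
            )
    return LabeledObjects(label_map=label_map, objects=objects)


def delete_object(mask: np.ndarray, object_id: int) -> np.ndarray:
    """Return a copy of ``mask`` with one labelled component erased.

    Mirrors the bulk-delete editing primitive: every pixel of the
    component is set false, all other components are untouched.
    """
    labeled = label_objects(mask)
    if not any(o.id == object_id for o in labeled.objects):
        raise KeyError(
            f"object id {object_id} not present (mask has {len(labeled)} objects)"
        )
    out = np.asarray(mask).astype(bool).copy()
    out[labeled.label_map == object_id] = False
    return out
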