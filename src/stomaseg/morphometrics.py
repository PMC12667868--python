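"""Per-stoma shape measurements and population summaries.

Each 8-connected mask component yields one record: area (pixel count),
perimeter (contour length with diagonal correction), and the
moment-ellipse descriptors — eccentricity ``sqrt(1 - (minor/major)^2)``
plus ellipse-equivalent major/minor axis lengths standing in for guard
cell complex length and width.  Supplying a pixel size converts the
records to physical units (lengths scale linearly, areas
quadratically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = ["MorphRecord", "PopulationSummary", "measure_objects", "summarize_population"]


@dataclass(frozen=True)
class MorphRecord:
    object_id: int
    area: float  # px² (or unit² when pixel_size given)
    perimeter: float
    eccentricity: float
    length: float  # moment-ellipse major axis
    width: float  # moment-ellipse minor axis
    centroid: tuple[float, float]


@dataclass
class PopulationSummary:
    n_stomata: int
    density: float  # count per unit of reference area
    stats: dict  # metric -> {mean, sd, q25, median, q75}; sd is NaN for n < 2


_METRICS = ("area", "perimeter", "eccentricity", "length", "width")


def measure_objects(mask: np.ndarray, pixel_size: float | None = None) -> list[MorphRecord]:
    """Measure every 8-connected component of a stomatal mask.

    ``pixel_size`` is the physical edge length of one pixel (e.g. µm/px);
    when given, lengths are reported in that unit and areas in its
    square.  An empty mask yields an empty list.
    """
    mask = np.asarray(mask).astype(bool)
    s = 1.0 if pixel_size is None else float(pixel_size)
    records = []
    for rp in regionprops(sk_label(mask, connectivity=2)):
        records.append(
            MorphRecord(
                object_id=int(rp.label),
                area=float(rp.area) * s * s,
                perimeter=float(rp.perimeter) * s,
                eccentricity=float(rp.eccentricity),
                length=float(rp.axis_major_length) * s,
                width=float(rp.axis_minor_length) * s,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return records


def summarize_population(records: list[MorphRecord], reference_area: float) -> PopulationSummary:
    """Population statistics plus stomatal density over ``reference_area``.

    The density denominator defaults to the full image area upstream;
    pass the tissue area instead when a tissue outline is available.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")
    n = len(records)
    stats: dict = {}
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in records], dtype=float)
        if n == 0:
            stats[m] = {k: float("nan") for k in ("mean", "sd", "q25", "median", "q75")}
        else:
            stats[m] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else float("nan"),
                "q25": float(np.quantile(vals, 0.25)),
                "median": float(np.quantile(vals, 0.5)),
                "q75": float(np.quantile(vals, 0.75)),
            }
    return PopulationSummary(n_stomata=n, density=n / reference_area, stats=stats)
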