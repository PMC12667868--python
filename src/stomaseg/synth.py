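"""Synthetic fluorescence-like epidermis scenes with ground-truth masks.

Real input images show a plasma-membrane reporter: bright polygonal
pavement-cell wall networks with stomata appearing as paired guard cells
around a dark pore slit.  The generator emulates that qualitative
structure — a seeded Voronoi-like tessellation rendered as bright ridges,
stomata drawn as bright-outlined filled ellipses split by a dark slit
along the major axis — so every downstream stage (tiling, training,
inference, post-processing, morphometrics, pair calling) is trainable and
testable without any real data.

Truth masks are regularised by a morphological open-then-close with a
small disk at generation time: guard-cell complex outlines are smooth and
spur-free, and because open-then-close is idempotent the ideal mask is a
fixed point of the default mask-repair smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import closing, disk, opening

from .io import LabeledObjects, label_objects

__all__ = ["SceneSpec", "SceneObject", "SyntheticScene", "generate_scene", "generate_toy_mask"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic epidermis scene.

    Defaults describe a realistic 20x-confocal field of a young
    cotyledon: stomatal complexes of 600-2400 px² (safely inside the
    250/3750 px post-processing size gates), moderately elongated guard
    cell pairs, and a pavement-cell tessellation of ~2 cells per 10⁴ px².
    """

    height: int = 320
    width: int = 320
    n_stomata: int = 6
    cluster_fraction: float = 0.0
    stoma_area_range: tuple[float, float] = (600.0, 2400.0)
    eccentricity_range: tuple[float, float] = (0.55, 0.85)
    wall_density: float = 2.0  # pavement cells per 1e4 px²
    noise_sigma: float = 8.0  # additive Gaussian noise, intensity units
    blur_sigma: float = 1.0  # px, optical blur
    n_distractors: int = 0  # pore-less immature look-alikes (hard negatives)
    intensity_field: bool = False  # low-frequency multiplicative shading
    border_clip: bool = False  # allow stomata to cross image borders
    truth_smooth_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("scene extent must be positive")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        lo, hi = self.stoma_area_range
        if not (0 < lo < hi):
            raise ValueError("stoma_area_range must be an increasing positive interval")
        elo, ehi = self.eccentricity_range
        if not (0.0 <= elo <= ehi < 1.0):
            raise ValueError("eccentricity_range must lie in [0, 1)")


@dataclass(frozen=True)
class SceneObject:
    """One truth-mask component: a single stoma or a touching cluster."""

    id: int
    centroid: tuple[float, float]
    area: int  # exact pixel count of the component
    eccentricity: float  # sampled target (NaN for clusters)
    is_cluster: bool
    n_members: int


@dataclass
class SyntheticScene:
    image: np.ndarray  # uint8 micrograph
    truth_mask: np.ndarray  # bool, components 1:1 with object_table
    object_table: list[SceneObject] = field(default_factory=list)

    @property
    def labeled(self) -> LabeledObjects:
        return label_objects(self.truth_mask)


def _ellipse_footprint(shape, center, a, b, theta):
    """Boolean raster of the ellipse with semi-axes a (major), b (minor)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_stoma(image, truth, center, area, ecc, theta, rng, pore=True):
    """Render one guard-cell pair; marks truth with the full footprint."""
    ratio = math.sqrt(1.0 - ecc**2)  # b/a
    a = math.sqrt(area / (math.pi * ratio))
    b = a * ratio
    fp = _ellipse_footprint(image.shape, center, a, b, theta)
    inner = _ellipse_footprint(image.shape, center, max(a - 2.0, 1.0), max(b - 2.0, 1.0), theta)
    rr, cc = np.ogrid[: image.shape[0], : image.shape[1]]
    ct, st = math.cos(theta), math.sin(theta)
    v = -(cc - center[1]) * st + (rr - center[0]) * ct  # minor-axis coordinate
    slit_half = rng.uniform(0.5, 1.5)  # dark pore slit 1-3 px wide
    slit = inner & (np.abs(v) <= slit_half)
    guard_fill = float(rng.uniform(130, 155))
    outline = float(rng.uniform(205, 235))
    image[fp & ~inner] = outline  # bright membrane outline
    image[inner] = guard_fill  # dense guard-cell membrane signal
    if pore:
        image[slit] = float(rng.uniform(15, 35))
        image[inner & (np.abs(v) > slit_half) & (np.abs(v) <= slit_half + 1.5)] = outline
        truth |= fp
    return fp


def _wall_network(shape, wall_density, rng):
    """Bright-ridge Voronoi-like tessellation emulating pavement cell walls."""
    h, w = shape
    n_cells = max(2, int(round(wall_density * h * w / 1e4)))
    pts = rng.uniform([0, 0], [h, w], size=(n_cells, 2))
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    _, lab = cKDTree(pts).query(grid)
    lab = lab.reshape(h, w)
    edges = np.zeros(shape, dtype=bool)
    edges[:-1, :] |= lab[:-1, :] != lab[1:, :]
    edges[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    return ndimage.binary_dilation(edges, structure=disk(1))


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene; bit-identical for identical ``spec`` (incl. seed).

    Raises ``RuntimeError`` if the requested stomata cannot be placed
    without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.full((h, w), 30.0)
    image[_wall_network((h, w), spec.wall_density, rng)] = rng.uniform(195, 225)

    lo, hi = spec.stoma_area_range
    # sample targets from the inner 80% of the interval so digitisation
    # and truth smoothing cannot push component areas outside the range
    lo_s, hi_s = lo + 0.1 * (hi - lo), lo - 0.1 * (hi - lo) + (hi - lo)
    elo, ehi = spec.eccentricity_range

    n_clusters = int(round(spec.cluster_fraction * spec.n_stomata))
    plan = [True] * n_clusters + [False] * (spec.n_stomata - n_clusters)

    truth = np.zeros((h, w), dtype=bool)
    placed: list[dict] = []  # {center, radius, ecc, is_cluster, n_members}
    max_tries = 200
    for is_cluster in plan:
        if is_cluster:
            n_members = int(rng.integers(2, 4))  # 2 or 3 touching stomata
            total = rng.uniform(max(lo_s, 900.0), hi_s)
            member_areas = [total / n_members] * n_members
            radius = math.sqrt(total / math.pi) * 1.6
        else:
            n_members = 1
            member_areas = [rng.uniform(lo_s, hi_s)]
            radius = math.sqrt(member_areas[0] / math.pi) * 1.5
        ecc = rng.uniform(elo, ehi)
        margin = 0 if spec.border_clip else radius + 4
        for attempt in range(max_tries):
            cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
            cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
            # truth components must stay >= 12 px apart so the generation-time
            # closing (radius 3) can never bridge two distinct objects
            if all(
                math.hypot(cy - p["center"][0], cx - p["center"][1])
                > radius + p["radius"] + 12
                for p in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place stoma {len(placed) + 1}/{spec.n_stomata} "
                f"after {max_tries} retries; reduce n_stomata or enlarge the scene"
            )
        theta = rng.uniform(0, math.pi)
        if is_cluster:
            # members strung along one axis, slightly overlapping so the
            # rendered complexes share a single truth component
            ratio = math.sqrt(1.0 - ecc**2)
            offs, pos = [], 0.0
            for k, ma in enumerate(member_areas):
                b_k = math.sqrt(ma * ratio / math.pi)
                if k:
                    pos += 1.7 * b_k
                offs.append(pos)
                pos += 0.0
            mid = offs[-1] / 2
            for k, ma in enumerate(member_areas):
                d = offs[k] - mid
                mcy = cy - d * math.sin(theta)
                mcx = cx + d * math.cos(theta)
                _draw_stoma(image, truth, (mcy, mcx), ma, ecc, theta + rng.uniform(-0.3, 0.3), rng)
        else:
            _draw_stoma(image, truth, (cy, cx), member_areas[0], ecc, theta, rng)
        placed.append(
            dict(center=(cy, cx), radius=radius, ecc=ecc, is_cluster=is_cluster, n_members=n_members)
        )

    for _ in range(spec.n_distractors):
        # immature, pore-less look-alike: outline only, never in the truth
        area = rng.uniform(150.0, 400.0)
        cy, cx = rng.uniform(20, h - 20), rng.uniform(20, w - 20)
        if any(math.hypot(cy - p["center"][0], cx - p["center"][1]) < p["radius"] + 25 for p in placed):
            continue
        _draw_stoma(image, truth, (cy, cx), area, rng.uniform(elo, ehi), rng.uniform(0, math.pi), rng, pore=False)

    if spec.truth_smooth_radius > 0:
        se = disk(spec.truth_smooth_radius)
        truth = closing(opening(truth, se), se)

    if spec.intensity_field:
        coarse = rng.uniform(0.7, 1.2, size=(4, 4))
        image *= ndimage.zoom(coarse, (h / 4, w / 4), order=3, grid_mode=True, mode="nearest")
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    labeled = label_objects(truth)
    if len(labeled) != spec.n_stomata:
        raise RuntimeError(
            f"truth mask has {len(labeled)} components for {spec.n_stomata} "
            "requested stomata (placement collision)"
        )
    # match placed objects to truth components via the label under each center
    members: dict[int, list[dict]] = {}
    for p in placed:
        lab = int(labeled.label_map[int(round(p["center"][0])), int(round(p["center"][1]))])
        if lab == 0:  # centre fell on the pore slit of a smoothed-away pixel
            dist = ndimage.distance_transform_edt(labeled.label_map == 0, return_indices=True)
            iy, ix = dist[1]
            r, c = int(round(p["center"][0])), int(round(p["center"][1]))
            lab = int(labeled.label_map[iy[r, c], ix[r, c]])
        members.setdefault(lab, []).append(p)
    table = []
    for obj in labeled.objects:
        mem = members.get(obj.id, [])
        p = mem[0] if mem else {}
        is_cluster = bool(p.get("is_cluster", False))
        table.append(
            SceneObject(
                id=obj.id,
                centroid=obj.centroid,
                area=obj.pixel_count,
                eccentricity=float("nan") if is_cluster else float(p.get("ecc", float("nan"))),
                is_cluster=is_cluster,
                n_members=int(p.get("n_members", 1)),
            )
        )
    return SyntheticScene(image=image, truth_mask=truth, object_table=table)


def generate_toy_mask(areas: list[int], height: int = 256, width: int = 256) -> np.ndarray:
    """Mask of well-separated rectangle-ish components with exact areas.

    Each requested area becomes one component: a near-square rectangle
    plus a partial extra row when the area is not a product of two
    near-equal integers.  Raises ``ValueError`` if the shapes cannot be
    packed into the canvas without touching.
    """
    mask = np.zeros((height, width), dtype=bool)
    r0, c0, row_h = 4, 4, 0
    for area in areas:
        if area < 1:
            raise ValueError("areas must be positive")
        side = max(1, int(math.floor(math.sqrt(area))))
        full_w = area // side
        rem = area - side * full_w
        box_h = side + (1 if rem else 0)
        box_w = max(full_w, rem)
        if c0 + box_w + 4 > width:
            r0, c0 = r0 + row_h + 4, 4
            row_h = 0
        if r0 + box_h + 4 > height or c0 + box_w + 4 > width:
            raise ValueError(f"cannot pack areas {areas} into {height}x{width} canvas")
        mask[r0 : r0 + side, c0 : c0 + full_w] = True
        if rem:
            mask[r0 + side, c0 : c0 + rem] = True
        row_h = max(row_h, box_h)
        c0 += box_w + 4
    return mask


def scene_batch(base: SceneSpec, n: int, seed: int) -> list[SyntheticScene]:
    """Generate ``n`` scenes with per-scene seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    return [generate_scene(replace(base, seed=s)) for s in seeds]
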