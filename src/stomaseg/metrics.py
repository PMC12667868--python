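"""Scoring of predicted masks against ground truth.

Two complementary views:

* **Per-pixel** — a contingency table (tp/fp/fn/tn), intersection over
  union (tp / (tp + fp + fn)), and a margin-normalised error: the total
  pixel error (fp + fn) divided by the number of "margin pixels", a thin
  band around every ground-truth object boundary where some inaccuracy
  is tolerated.  A fold error magnitude below 1 means the discrepancy
  fits inside that tolerance band.

* **Per-object** — each ground-truth stoma is called Complete (matched,
  boundary within a 3 px tolerance everywhere), Partial (matched but
  deviating by more than the tolerance somewhere), or Miss (no matching
  prediction); predictions matching no truth object are False.  Complete
  and Partial both count as positive identifications.

A colour concordance overlay renders false negatives blue, false
positives orange, true positives pink and true negatives black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .io import LabeledObjects, label_objects

__all__ = [
    "PixelContingency",
    "MarginMetrics",
    "ObjectCall",
    "OVERLAY_PALETTE",
    "pixel_contingency",
    "margin_metrics",
    "fold_error_from_counts",
    "match_objects",
    "classify_annotations",
    "concordance_overlay",
    "aggregate_object_counts",
    "evaluate_dataset",
]

OVERLAY_PALETTE = {
    "tp": (255, 128, 255),  # pink
    "fp": (255, 128, 0),  # orange
    "fn": (0, 0, 255),  # blue
    "tn": (0, 0, 0),  # black
}


@dataclass(frozen=True)
class PixelContingency:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def iou(self) -> float:
        denom = self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    @property
    def annotated_pixels(self) -> int:
        """Pixels marked in ground truth or prediction (their union)."""
        return self.tp + self.fp + self.fn

    @property
    def total_pixel_error(self) -> int:
        """Discrepant pixels between the two masks."""
        return self.fp + self.fn


@dataclass(frozen=True)
class MarginMetrics:
    margin_pixels: int
    fold_error_magnitude: float


@dataclass(frozen=True)
class ObjectCall:
    object_id: int
    call: str  # Complete | Partial | False | Miss
    matched_id: int | None
    max_boundary_deviation: float


def _check_shapes(truth: np.ndarray, pred: np.ndarray):
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    return truth, pred


def pixel_contingency(truth: np.ndarray, pred: np.ndarray) -> PixelContingency:
    """tp/fp/fn/tn pixel counts for one (ground truth, prediction) pair."""
    truth, pred = _check_shapes(truth, pred)
    tp = int(np.count_nonzero(truth & pred))
    fp = int(np.count_nonzero(~truth & pred))
    fn = int(np.count_nonzero(truth & ~pred))
    tn = truth.size - tp - fp - fn
    return PixelContingency(tp=tp, fp=fp, fn=fn, tn=tn)


def fold_error_from_counts(total_pixel_error: int, margin_pixels: int) -> float:
    """Total pixel error normalised by the margin-band size."""
    if margin_pixels <= 0:
        raise ValueError("margin_pixels must be positive")
    return total_pixel_error / margin_pixels


def margin_metrics(
    truth: np.ndarray, contingency: PixelContingency, band_radius: int = 1
) -> MarginMetrics:
    """Margin band (dilate XOR erode of the truth) and fold error.

    The band hugs every ground-truth object boundary; with the default
    radius 1 it is the ~2-3 px ring where annotator and machine may
    legitimately disagree.
    """
    truth = np.asarray(truth).astype(bool)
    if not truth.any():
        raise ValueError("ground truth is empty; margin band undefined")
    se = disk(band_radius)
    band = ndimage.binary_dilation(truth, se) ^ ndimage.binary_erosion(truth, se)
    margin = int(np.count_nonzero(band))
    return MarginMetrics(
        margin_pixels=margin,
        fold_error_magnitude=fold_error_from_counts(contingency.total_pixel_error, margin),
    )


def match_objects(
    truth_objs: LabeledObjects, pred_objs: LabeledObjects
) -> tuple[list[tuple[int, int | None]], list[int]]:
    """Greedy 1:1 matching of truth and prediction components by IoU.

    Pairs are taken in order of descending pairwise IoU; zero-overlap
    pairs are never matched.  Returns ``(matches, unmatched_pred_ids)``
    where ``matches`` has one ``(truth_id, pred_id or None)`` entry per
    truth object.
    """
    tmap, pmap = truth_objs.label_map, pred_objs.label_map
    if tmap.shape != pmap.shape:
        raise ValueError("label maps must share a canvas")
    tcounts = {o.id: o.pixel_count for o in truth_objs.objects}
    pcounts = {o.id: o.pixel_count for o in pred_objs.objects}
    # pairwise intersections via joint histogram of the two label maps
    both = (tmap > 0) & (pmap > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        t_ids = tmap[both].ravel()
        p_ids = pmap[both].ravel()
        keys, counts = np.unique(np.stack([t_ids, p_ids]), axis=1, return_counts=True)
        for (ti, pi), n in zip(keys.T, counts):
            pairs[(int(ti), int(pi))] = int(n)
    scored = sorted(
        (
            (inter / (tcounts[ti] + pcounts[pi] - inter), ti, pi)
            for (ti, pi), inter in pairs.items()
        ),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    matched_t: dict[int, int] = {}
    used_p: set[int] = set()
    for _, ti, pi in scored:
        if ti not in matched_t and pi not in used_p:
            matched_t[ti] = pi
            used_p.add(pi)
    matches = [(o.id, matched_t.get(o.id)) for o in truth_objs.objects]
    unmatched_pred = [o.id for o in pred_objs.objects if o.id not in used_p]
    return matches, unmatched_pred


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def _max_boundary_deviation(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric max distance between the boundaries of two components."""
    ba, bb = _boundary(a), _boundary(b)
    if not ba.any() or not bb.any():
        return float("inf")
    da = ndimage.distance_transform_edt(~ba)
    db = ndimage.distance_transform_edt(~bb)
    return float(max(da[bb].max(), db[ba].max()))


def classify_annotations(
    truth: np.ndarray, pred: np.ndarray, tol: float = 3.0
) -> tuple[list[ObjectCall], dict]:
    """Call every truth object Complete/Partial/Miss and every stray
    prediction False.

    A matched pair is Complete when the symmetric maximum boundary
    deviation between the two outlines is at most ``tol`` pixels, else
    Partial.  The summary reports ``pct_accurate`` as Complete (hit) over
    total truth objects, and ``positives`` as Complete + Partial.
    """
    truth, pred = _check_shapes(truth, pred)
    tobj = label_objects(truth)
    pobj = label_objects(pred)
    matches, stray = match_objects(tobj, pobj)
    calls: list[ObjectCall] = []
    n_hit = n_partial = 0
    for ti, pi in matches:
        if pi is None:
            calls.append(ObjectCall(ti, "Miss", None, float("inf")))
            continue
        dev = _max_boundary_deviation(tobj.label_map == ti, pobj.label_map == pi)
        if dev <= tol:
            n_hit += 1
            calls.append(ObjectCall(ti, "Complete", pi, dev))
        else:
            n_partial += 1
            calls.append(ObjectCall(ti, "Partial", pi, dev))
    for pi in stray:
        calls.append(ObjectCall(pi, "False", None, float("inf")))
    total = len(tobj)
    summary = {
        "hit": n_hit,
        "partial": n_partial,
        "miss": total - n_hit - n_partial,
        "false": len(stray),
        "total": total,
        "positives": n_hit + n_partial,
        "pct_accurate": 100.0 * n_hit / total if total else float("nan"),
    }
    return calls, summary


def concordance_overlay(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """RGB raster: FN blue, FP orange, TP pink, TN black."""
    truth, pred = _check_shapes(truth, pred)
    out = np.zeros((*truth.shape, 3), dtype=np.uint8)
    out[truth & ~pred] = OVERLAY_PALETTE["fn"]
    out[~truth & pred] = OVERLAY_PALETTE["fp"]
    out[truth & pred] = OVERLAY_PALETTE["tp"]
    return out


def aggregate_object_counts(rows: pd.DataFrame) -> dict:
    """TOTAL-row statistics from per-image Hit/Miss/Partial(/False) counts.

    Overall ``pct_accurate`` is the pooled Hit / Total (not the mean of
    per-image percentages); ``positives`` pools Hit + Partial.
    """
    hit = int(rows["hit"].sum())
    miss = int(rows["miss"].sum())
    partial = int(rows["partial"].sum())
    total = int(rows["total"].sum()) if "total" in rows else hit + miss + partial
    false = rows["false"] if "false" in rows else pd.Series(0, index=rows.index)
    return {
        "hit": hit,
        "miss": miss,
        "partial": partial,
        "false": int(false.sum()),
        "total": total,
        "positives": hit + partial,
        "pct_accurate": 100.0 * hit / total if total else float("nan"),
        "pct_positive": 100.0 * (hit + partial) / total if total else float("nan"),
        "mean_misses": float(rows["miss"].mean()),
        "max_misses": int(rows["miss"].max()),
        "mean_false": float(false.mean()),
    }


def evaluate_dataset(
    pairs: list[tuple[np.ndarray, np.ndarray]], tol: float = 3.0, band_radius: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Per-image report plus pooled TOTAL summary for a validation set.

    One row per (truth, prediction) pair with the per-object counts,
    % Accurate, IoU and margin metrics; the TOTAL dict pools the object
    counts and averages the per-pixel scores.
    """
    if not pairs:
        raise ValueError("no (truth, prediction) pairs given")
    rows = []
    for i, (truth, pred) in enumerate(pairs):
        cont = pixel_contingency(truth, pred)
        _, summ = classify_annotations(truth, pred, tol=tol)
        row = {
            "image": i,
            "hit": summ["hit"],
            "miss": summ["miss"],
            "partial": summ["partial"],
            "false": summ["false"],
            "total": summ["total"],
            "pct_accurate": summ["pct_accurate"],
            "iou": cont.iou,
            "annotated_pixels": cont.annotated_pixels,
            "total_pixel_error": cont.total_pixel_error,
        }
        if np.asarray(truth).any():
            mm = margin_metrics(truth, cont, band_radius=band_radius)
            row["margin_pixels"] = mm.margin_pixels
            row["fold_error_magnitude"] = mm.fold_error_magnitude
        rows.append(row)
    df = pd.DataFrame(rows)
    total = aggregate_object_counts(df)
    total["mean_iou"] = float(df["iou"].mean())
    return df, total
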