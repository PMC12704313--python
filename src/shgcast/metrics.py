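"""Segmentation-quality metrics: Dice, IoU, Hausdorff, sensitivity, specificity.

Conventions, pinned down because they matter for comparability:

* The Hausdorff distance is the exact symmetric worst case
  ``max(sup_a d(a, B), sup_b d(b, A))`` over foreground voxel centers,
  Euclidean. Percentile variants (e.g. HD95) are available via the
  ``percentile`` argument but are never the default.
* Default distance units are voxels with isotropic spacing 1 in every axis
  (matching how pixel/voxel Hausdorff values are usually reported);
  ``units="physical"`` scales each axis by the voxel size instead.
* Both masks empty: DSC = IoU = 1, sensitivity reported as 1, Hausdorff 0.
  Exactly one mask empty: Hausdorff is +inf (flagged), the overlap metrics
  are still computed.
* Aggregation over several mask pairs is either the unweighted mean of
  per-item metrics (default) or pooled confusion counts; a single printed
  (DSC, IoU) pair only obeys the identity ``dsc = 2*iou/(1+iou)`` when it
  comes from pooled counts or a single pair, so the choice is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "confusion_counts",
    "evaluate_masks",
    "hausdorff_distance",
    "aggregate_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegmentationMetrics:
    dsc: float
    iou: float
    hausdorff: float
    sensitivity: float
    specificity: float
    units_flag: str = "voxel"
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {
            "dsc": self.dsc,
            "iou": self.iou,
            "hausdorff": self.hausdorff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "units": self.units_flag,
        }
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp, "fp": self.counts.fp,
                "fn": self.counts.fn, "tn": self.counts.tn,
            }
        return d


def _as_bool(mask) -> np.ndarray:
    arr = getattr(mask, "labels", mask)
    return np.asarray(arr) > 0


def confusion_counts(pred, ref) -> ConfusionCounts:
    """Voxelwise confusion counts between two binary masks of equal shape."""
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def hausdorff_distance(
    a, b,
    units: str = "voxel",
    voxel_size: tuple[float, float, float] | None = None,
    percentile: float = 100.0,
) -> float:
    """Symmetric Hausdorff distance between the foregrounds of two masks.

    Computed via exact Euclidean distance transforms: for each mask the
    distance of every foreground voxel of the other mask to its nearest
    foreground voxel, then the worst case (or the given percentile of the
    per-voxel distances, taken on each direction before the outer max).
    Raises ``ValueError`` if either mask is empty.
    """
    am, bm = _as_bool(a), _as_bool(b)
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch: {am.shape} vs {bm.shape}")
    if not am.any() or not bm.any():
        raise ValueError("hausdorff_distance requires two non-empty masks")
    if units == "physical":
        if voxel_size is None:
            voxel_size = getattr(a, "voxel_size", None)
            vb = getattr(b, "voxel_size", None)
            if voxel_size is None or vb is None or tuple(voxel_size) != tuple(vb):
                raise ValueError("physical units need matching voxel sizes")
        sampling = tuple(voxel_size)
    elif units == "voxel":
        sampling = (1.0,) * am.ndim
    else:
        raise ValueError(f"unknown units {units!r}")
    dt_b = ndi.distance_transform_edt(~bm, sampling=sampling)
    dt_a = ndi.distance_transform_edt(~am, sampling=sampling)
    if percentile >= 100.0:
        d_ab = dt_b[am].max()
        d_ba = dt_a[bm].max()
    else:
        d_ab = np.percentile(dt_b[am], percentile)
        d_ba = np.percentile(dt_a[bm], percentile)
    return float(max(d_ab, d_ba))


def evaluate_masks(
    pred, ref,
    units: str = "voxel",
    voxel_size: tuple[float, float, float] | None = None,
) -> SegmentationMetrics:
    """All five metrics for a (prediction, reference) mask pair.

    DSC = 2tp/(2tp+fp+fn); IoU = tp/(tp+fp+fn); sensitivity = tp/(tp+fn);
    specificity = tn/(tn+fp). Empty-vs-empty is scored perfect; one-sided
    emptiness gives Hausdorff +inf while the ratio metrics are still defined.
    """
    c = confusion_counts(pred, ref)
    p_any = _as_bool(pred).any()
    r_any = _as_bool(ref).any()
    if not p_any and not r_any:
        dsc = iou = 1.0
        sens = 1.0
        spec = 1.0 if c.tn + c.fp else 1.0
        hd = 0.0
    else:
        dsc = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
        iou = c.tp / (c.tp + c.fp + c.fn)
        sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0
        spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 1.0
        if p_any and r_any:
            hd = hausdorff_distance(pred, ref, units=units, voxel_size=voxel_size)
        else:
            hd = float("inf")
    return SegmentationMetrics(
        dsc=float(dsc), iou=float(iou), hausdorff=hd,
        sensitivity=float(sens), specificity=float(spec),
        units_flag=units, counts=c,
    )


def aggregate_metrics(
    pairs: list[tuple],
    units: str = "voxel",
    mode: str = "mean",
) -> SegmentationMetrics:
    """Aggregate metrics over several (pred, ref) pairs.

    ``mode="mean"`` averages per-item metrics (items with an infinite
    Hausdorff propagate inf); ``mode="pooled"`` sums confusion counts first,
    which preserves the DSC-IoU identity but weights items by size. Pooled
    Hausdorff is the max over items.
    """
    if not pairs:
        raise ValueError("no mask pairs to aggregate")
    items = [evaluate_masks(p, r, units=units) for p, r in pairs]
    if mode == "mean":
        return SegmentationMetrics(
            dsc=float(np.mean([m.dsc for m in items])),
            iou=float(np.mean([m.iou for m in items])),
            hausdorff=float(np.mean([m.hausdorff for m in items])),
            sensitivity=float(np.mean([m.sensitivity for m in items])),
            specificity=float(np.mean([m.specificity for m in items])),
            units_flag=units,
        )
    if mode == "pooled":
        tp = sum(m.counts.tp for m in items)
        fp = sum(m.counts.fp for m in items)
        fn = sum(m.counts.fn for m in items)
        tn = sum(m.counts.tn for m in items)
        denom = 2 * tp + fp + fn
        union = tp + fp + fn
        return SegmentationMetrics(
            dsc=2.0 * tp / denom if denom else 1.0,
            iou=tp / union if union else 1.0,
            hausdorff=float(max(m.hausdorff for m in items)),
            sensitivity=tp / (tp + fn) if tp + fn else 1.0,
            specificity=tn / (tn + fp) if tn + fp else 1.0,
            units_flag=units,
            counts=ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn),
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")
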