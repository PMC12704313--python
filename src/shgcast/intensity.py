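"""SHG intensity quantification in 2D and 3D, and stage-comparison statistics.

Implements the standard collagen-intensity readouts for endometrial SHG
scans: mean intensity over rectangular or circular regions of interest
(ROIs), the cage-to-stroma intensity ratio (mean of cage-ROI means divided
by mean of stroma-ROI means), four-direction "compass" thickness of the
fibrillar collagen rim around a gland cross-section, global-mean ratio maps,
the 3D fold-change of a gland-cluster sub-stack, and the one-way
ANOVA + Tukey pipeline used to compare estrous stages.

Averaging convention: multi-ROI intensities are the unweighted mean of the
per-ROI means, never a pooled-voxel mean, mirroring how repeated manual
measurements are averaged per sample before group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .imgio import LabelVolume, VolumeScan

__all__ = [
    "RoiBox",
    "RoiDisk",
    "RoiStats",
    "CompassMeasurement",
    "StageComparison",
    "roi_mean",
    "averaged_roi_intensity",
    "cage_to_stroma_ratio",
    "compass_thickness",
    "ratio_map",
    "cage_fold_change_3d",
    "compare_stages",
    "auto_place_rois",
]


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box ROI: 0-based ``origin`` (z, y, x), half-open ``size``.

    For a 2D (single-slice) ROI use ``size[0] == 1``.
    """

    origin: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self):
        if any(s < 1 for s in self.size):
            raise ValueError("all ROI sizes must be >= 1")
        if any(o < 0 for o in self.origin):
            raise ValueError("ROI origin must be non-negative")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        for o, s, n in zip(self.origin, self.size, shape):
            if o + s > n:
                raise ValueError(f"ROI {self} extends outside volume of shape {shape}")


@dataclass(frozen=True)
class RoiDisk:
    """Circular in-plane ROI replicated over a half-open slice interval."""

    center: tuple[float, float]  # (y, x) voxels
    radius: float  # voxels
    z_range: tuple[int, int]  # half-open

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("disk radius must be > 0")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("empty z_range")

    def plane_mask(self, plane_shape: tuple[int, int]) -> np.ndarray:
        cy, cx = self.center
        if (cy - self.radius < -0.5 or cx - self.radius < -0.5
                or cy + self.radius > plane_shape[0] - 0.5
                or cx + self.radius > plane_shape[1] - 0.5):
            raise ValueError(f"disk {self} extends outside slice bounds {plane_shape}")
        yy, xx = np.ogrid[: plane_shape[0], : plane_shape[1]]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    min: float
    max: float
    count: int


def _roi_values(scan: VolumeScan, roi: RoiBox | RoiDisk) -> np.ndarray:
    vox = scan.voxels
    if isinstance(roi, RoiBox):
        roi.check_inside(vox.shape)
        return vox[roi.slices()].ravel()
    z0, z1 = roi.z_range
    if z0 < 0 or z1 > vox.shape[0]:
        raise ValueError(f"disk z_range {roi.z_range} outside volume")
    mask = roi.plane_mask(vox.shape[1:])
    return vox[z0:z1, mask].ravel()


def roi_mean(scan: VolumeScan, roi: RoiBox | RoiDisk) -> RoiStats:
    """Mean intensity (plus sd/min/max/count) over one ROI."""
    vals = _roi_values(scan, roi).astype(np.float64)
    return RoiStats(
        mean=float(vals.mean()), sd=float(vals.std()),
        min=float(vals.min()), max=float(vals.max()), count=int(vals.size),
    )


def averaged_roi_intensity(
    scan: VolumeScan, rois: list[RoiBox | RoiDisk]
) -> tuple[float, list[float]]:
    """Unweighted mean of per-ROI mean intensities (not a pooled-voxel mean).

    Returns ``(average, per_roi_means)``.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    means = [roi_mean(scan, r).mean for r in rois]
    return float(np.mean(means)), means


def cage_to_stroma_ratio(
    scan: VolumeScan,
    cage_rois: list[RoiBox | RoiDisk],
    stroma_rois: list[RoiBox | RoiDisk],
) -> float:
    """Averaged cage-ROI intensity divided by averaged stroma-ROI intensity."""
    cage_avg, _ = averaged_roi_intensity(scan, cage_rois)
    stroma_avg, _ = averaged_roi_intensity(scan, stroma_rois)
    if stroma_avg == 0:
        raise ZeroDivisionError("stroma average intensity is zero")
    return cage_avg / stroma_avg


@dataclass(frozen=True)
class CompassMeasurement:
    """Four orthogonal rim thicknesses (um) and their arithmetic mean.

    ``flags`` marks directions where the ray left the image before meeting a
    rim (thickness reported as 0 there).
    """

    t_north: float
    t_south: float
    t_east: float
    t_west: float
    flags: tuple[bool, bool, bool, bool] = (False, False, False, False)

    @property
    def mean_thickness(self) -> float:
        return (self.t_north + self.t_south + self.t_east + self.t_west) / 4.0


def _ray_thickness(profile: np.ndarray, threshold: float, spacing: float) -> tuple[float, bool]:
    """Length (um) of the first contiguous >= threshold run along a ray that
    starts inside the gland; 0 with a flag if the ray exits first."""
    above = profile >= threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0.0, True
    start = idx[0]
    run = 0
    for v in above[start:]:
        if not v:
            break
        run += 1
    return run * spacing, False


def compass_thickness(
    slice_image: np.ndarray,
    gland_center: tuple[int, int],
    threshold: float | None = None,
    pixel_size: tuple[float, float] = (1.0, 1.0),
) -> CompassMeasurement:
    """Cage rim thickness north/south/east/west of a gland cross-section.

    From ``gland_center`` (which must lie in a below-threshold interior),
    each of the four axis-aligned rays skips interior pixels and measures the
    physical length of the first contiguous run of pixels at or above
    ``threshold`` — the collagen rim. ``threshold=None`` uses Otsu's value on
    the slice (the manual procedure relied on visually clear boundaries,
    which is not algorithmic). North/south travel along -y/+y, east/west
    along +x/-x; each length is the pixel count times that axis' spacing.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(img))
    y0, x0 = gland_center
    if img[y0, x0] >= threshold:
        raise ValueError("gland_center must lie in a below-threshold interior region")
    sy, sx = pixel_size
    north = _ray_thickness(img[y0::-1, x0], threshold, sy)
    south = _ray_thickness(img[y0:, x0], threshold, sy)
    east = _ray_thickness(img[y0, x0:], threshold, sx)
    west = _ray_thickness(img[y0, x0::-1], threshold, sx)
    return CompassMeasurement(
        t_north=north[0], t_south=south[0], t_east=east[0], t_west=west[0],
        flags=(north[1], south[1], east[1], west[1]),
    )


def ratio_map(image: np.ndarray) -> np.ndarray:
    """Divide an image (2D or 3D) by its global mean gray value.

    The returned map has mean exactly 1 (to float tolerance). Display
    clipping (e.g. to the 1-50-fold range) is presentation only and never
    applied here.
    """
    img = np.asarray(image, dtype=np.float64)
    m = img.mean()
    if m <= 0:
        raise ValueError("ratio_map requires a positive image mean")
    return img / m


def cage_fold_change_3d(
    scan: VolumeScan,
    substack: tuple[int, int],
    roi: RoiDisk,
    normalizer: str = "substack",
) -> float:
    """SHG intensity fold change of a gland-cluster ROI within a sub-stack.

    The sub-stack (half-open z interval) is divided by a normalizing mean
    gray value and the mean of the normalized voxels inside the circular ROI
    across the sub-stack is returned. ``normalizer="substack"`` (default)
    uses the whole sub-stack mean, so the result is the fold change of the
    gland-cluster region relative to the surrounding tissue;
    ``normalizer="roi"`` uses the ROI-restricted mean, which normalizes the
    measured region to itself (the result is then identically 1 — see the
    methods note on this ambiguity).
    """
    z0, z1 = substack
    if z0 < 0 or z1 > scan.shape[0] or z1 <= z0:
        raise ValueError(f"substack {substack} outside scan")
    sub = scan.voxels[z0:z1].astype(np.float64)
    mask = roi.plane_mask(sub.shape[1:])
    rz0 = max(roi.z_range[0] - z0, 0)
    rz1 = min(roi.z_range[1] - z0, sub.shape[0])
    if rz1 <= rz0:
        raise ValueError("ROI z_range does not intersect the substack")
    if normalizer == "substack":
        norm = sub.mean()
    elif normalizer == "roi":
        norm = sub[rz0:rz1, mask].mean()
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if norm == 0:
        raise ZeroDivisionError("normalizing mean gray value is zero")
    return float((sub[rz0:rz1, mask] / norm).mean())


@dataclass
class StageComparison:
    """Normality/variance diagnostics plus ANOVA and Tukey post hoc results."""

    groups: dict[str, list[float]]
    shapiro_p: dict[str, float | None]
    levene_p: float
    anova_F: float
    anova_p: float
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)


def compare_stages(records: dict[str, list[float]]) -> StageComparison:
    """One-way ANOVA with Tukey HSD across named groups.

    Per group: Shapiro-Wilk normality p (``None`` with fewer than 3 values,
    where the test is undefined). Across groups: Levene's test centered at
    the mean, the one-way ANOVA F and p, and Tukey-adjusted pairwise p
    values. Every group needs at least 2 values.
    """
    if len(records) < 2:
        raise ValueError("need at least two groups")
    for name, vals in records.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in records.items()}
    shapiro_p: dict[str, float | None] = {}
    for name, vals in arrays.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            shapiro_p[name] = float(stats.shapiro(vals).pvalue)
        else:
            shapiro_p[name] = None
    with np.errstate(invalid="ignore", divide="ignore"):
        levene_p = float(stats.levene(*arrays.values(), center="mean").pvalue)
        f_res = stats.f_oneway(*arrays.values())
    if math.isnan(levene_p):  # all spreads zero
        levene_p = 1.0
    anova_F = float(f_res.statistic)
    anova_p = float(f_res.pvalue)
    if math.isnan(anova_F):  # zero between- and within-group variance
        anova_F, anova_p = 0.0, 1.0

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey: dict[tuple[str, str], float] = {}
    if np.ptp(values) > 0:
        res = pairwise_tukeyhsd(values, labels)
        for row, p in zip(res.summary().data[1:], res.pvalues):
            tukey[(str(row[0]), str(row[1]))] = float(p)
    else:
        names = sorted(arrays)
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                tukey[(g1, g2)] = 1.0
    return StageComparison(
        groups={k: list(map(float, v)) for k, v in arrays.items()},
        shapiro_p=shapiro_p, levene_p=levene_p,
        anova_F=anova_F, anova_p=anova_p, tukey=tukey,
    )


def auto_place_rois(
    labels: LabelVolume,
    class_value: int,
    size: tuple[int, int, int],
    n: int,
    seed: int | np.random.Generator = 0,
    shrink_on_failure: bool = True,
    avoid: np.ndarray | None = None,
    avoid_margin_um: float = 0.0,
) -> list[RoiBox]:
    """Place ``n`` box ROIs entirely inside one label class.

    Replaces the manual ROI placement of the original protocol with a
    reproducible draw: valid origins are those whose whole box lies in the
    class (found with a minimum filter); ``n`` are sampled without
    replacement. If no placement of the requested size exists the box is
    halved per axis (down to a single voxel) before giving up. ROIs may
    overlap, as repeated manual measurements may. ``avoid`` (a boolean mask,
    e.g. the negative space) excludes voxels within ``avoid_margin_um`` of
    it, mirroring stromal measurements taken away from the glands.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = labels.mask(class_value)
    if avoid is not None and avoid.any():
        dist = ndi.distance_transform_edt(~avoid, sampling=labels.voxel_size)
        mask = mask & (dist > avoid_margin_um)
    size = tuple(int(s) for s in size)
    while True:
        ok = ndi.minimum_filter(
            mask.astype(np.uint8), size=size, mode="constant", cval=0
        ).astype(bool)
        # minimum_filter centers the footprint; convert centers to origins.
        centers = np.argwhere(ok)
        if centers.size:
            break
        if not shrink_on_failure or size == (1, 1, 1):
            raise ValueError(
                f"no box of size {size} fits inside class {class_value}"
            )
        size = tuple(max(1, s // 2) for s in size)
    pick = rng.choice(len(centers), size=min(n, len(centers)), replace=len(centers) < n)
    rois = []
    for i in np.atleast_1d(pick):
        c = centers[i]
        # scipy centers a size-s window at i - s//2
        origin = tuple(int(cc - s // 2) for cc, s in zip(c, size))
        origin = tuple(
            int(np.clip(o, 0, dim - s))
            for o, s, dim in zip(origin, size, mask.shape)
        )
        rois.append(RoiBox(origin=origin, size=size))
    return rois
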