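"""Synthetic SHG endometrium phantoms with known gland/lumen ground truth.

The phantom emulates the structures a second-harmonic-generation scan of
cleared mouse uterus shows: speckled fibrillar-collagen signal in the
endometrial stroma, uterine glands as near-zero "holes" wrapped in a bright
fibrillar collagen cage, a central lumen, an intense myometrial shell, and
optional depth-dependent attenuation. Gland interiors and the lumen carry no
fibrillar collagen and therefore no signal — the negative impression that
the casting modules reconstruct.

Estrous-stage presets encode the directional findings of the source imaging
study: the cage/stroma intensity ratio and the cage thickness peak in
estrus, and the cage becomes fragmented (discontinuous around the gland rim)
in diestrus. Gland geometry (random-walk centerlines protruding from near
the lumen, terminal lobes) is qualitative: no quantitative gland morphometry
is published, so all geometric parameters are exposed with documented
defaults.

Class labels: 0 stroma, 1 gland interior, 2 cage, 3 lumen, 4 myometrium.
The segmentation target ("negative space") is the union of classes 1 and 3.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .imgio import LabelVolume, VolumeScan

__all__ = [
    "STAGES",
    "PHANTOM_CLASS_MAP",
    "PhantomParams",
    "PhantomTruth",
    "PhantomPlacementError",
    "stage_preset",
    "generate_phantom",
    "truth_negative_space",
]

STAGES = ("proestrus", "estrus", "metestrus", "diestrus")

PHANTOM_CLASS_MAP = {
    0: "stroma",
    1: "gland_interior",
    2: "cage",
    3: "lumen",
    4: "myometrium",
}

STROMA, GLAND, CAGE, LUMEN, MYOMETRIUM = 0, 1, 2, 3, 4


class PhantomPlacementError(RuntimeError):
    """Raised when glands cannot be placed inside the endometrium."""


@dataclass
class PhantomParams:
    """Generator parameters. Lengths are micrometres, intensities arbitrary units.

    The cage has pre-noise intensity exactly ``cage_ratio * stroma_mean`` and
    gland/lumen interiors sit far below stroma, so class-masked means on the
    generated volume recover ``cage_ratio`` directly.
    """

    stage: str = "custom"
    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 0.79, 0.79)
    n_glands: int = 5
    gland_radius: tuple[float, float] = (5.0, 7.0)
    gland_length: tuple[float, float] = (30.0, 60.0)
    lobes_per_gland: tuple[int, int] = (1, 3)
    lobe_radius: tuple[float, float] = (6.0, 9.0)
    centerline_step: float = 2.0
    centerline_curvature: float = 0.35  # radians per step
    cage_thickness: float = 3.0
    cage_ratio: float = 1.5  # cage mean / stroma mean, pre-noise
    cage_continuity: float = 1.0  # fraction of cage surface retained
    cage_gap_level: float = 0.1  # intensity of collagen-poor gaps, x stroma_mean
    stroma_mean: float = 1000.0
    stroma_texture_scale: float = 1.5
    lumen_present: bool = True
    lumen_halfwidth: float = 12.0
    lumen_gap: float = 2.0  # stroma gap between lumen and gland stalks
    myometrium_present: bool = True
    myometrium_multiplier: float = 2.0
    myometrium_thickness: float = 6.0
    attenuation: float = 0.005  # fractional signal loss per um of depth
    compensated: bool = True  # laser compensation flattens the depth profile
    noise_sd: float = 50.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES + ("custom",):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.cage_ratio <= 0:
            raise ValueError("cage_ratio must be > 0")
        if not 0.0 <= self.cage_continuity <= 1.0:
            raise ValueError("cage_continuity must lie in [0, 1]")
        for name in ("centerline_step", "cage_thickness", "stroma_mean",
                     "stroma_texture_scale", "lumen_halfwidth",
                     "myometrium_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_glands < 0 or self.noise_sd < 0:
            raise ValueError("n_glands and noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """A generated scan, its per-structure labels and the parameters used."""

    scan: VolumeScan
    labels: LabelVolume
    params: PhantomParams


# Stage presets. cage_ratio spans the published 0.87-2.90-fold cage/stroma
# range (maximal in estrus, sub-unity in diestrus); cage thickness peaks in
# estrus; cage continuity is lowest in diestrus, whose fragmented cages are
# the documented failure mode of negative-space segmentation. Stromal
# fibrillar signal itself is highest in estrus and lowest in diestrus while
# the noise floor (same acquisition settings for every stage) stays fixed,
# so diestrus scans carry genuinely less contrast.
_STAGE_PRESETS: dict[str, dict[str, float]] = {
    "proestrus": dict(cage_ratio=1.6, cage_thickness=3.0, cage_continuity=0.9,
                      stroma_mean=800.0),
    "estrus": dict(cage_ratio=2.9, cage_thickness=4.0, cage_continuity=1.0,
                   stroma_mean=1000.0),
    "metestrus": dict(cage_ratio=1.3, cage_thickness=2.5, cage_continuity=0.8,
                      stroma_mean=700.0),
    "diestrus": dict(cage_ratio=0.9, cage_thickness=2.0, cage_continuity=0.5,
                     stroma_mean=500.0),
}


def stage_preset(stage: str, **overrides) -> PhantomParams:
    """Parameter preset for one estrous stage.

    Presets satisfy: cage_ratio(estrus) > cage_ratio(proestrus) >=
    cage_ratio(metestrus) > cage_ratio(diestrus); estrus has the thickest
    cage; diestrus the least continuous one. Keyword overrides replace any
    field (e.g. ``seed=7`` or ``noise_sd=0``).
    """
    if stage not in _STAGE_PRESETS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return PhantomParams(stage=stage, **{**_STAGE_PRESETS[stage], **overrides})


def _uniform(rng: np.random.Generator, lohi: Sequence[float]) -> float:
    lo, hi = lohi
    return float(rng.uniform(lo, hi))


def _stamp_ball(mask: np.ndarray, center: np.ndarray, radius_um: float,
                voxel_size: np.ndarray) -> None:
    """Set voxels within radius_um (physical) of center (voxel coords) to True."""
    r_vox = radius_um / voxel_size
    lo = np.maximum(np.floor(center - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_vox).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, voxel_size))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius_um**2


def _speckle(shape, scale_vox, rng: np.random.Generator) -> np.ndarray:
    """Band-limited multiplicative texture, mean 1, sd ~0.18, strictly positive."""
    g = ndi.gaussian_filter(rng.standard_normal(shape), sigma=scale_vox)
    sd = g.std()
    if sd > 0:
        g /= sd
    return np.clip(1.0 + 0.18 * g, 0.2, None)


def _grow_centerline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    step_um: float,
    curvature: float,
    voxel_size: np.ndarray,
    inside,
) -> list[np.ndarray]:
    """Random-walk centerline (voxel coords); steps leaving the endometrium
    are re-drawn with fresh directions, so the walk stays inside."""
    points = [start.copy()]
    p = start.copy()
    d = direction / np.linalg.norm(direction)
    for _ in range(n_steps):
        placed = False
        for _try in range(12):
            dd = d + curvature * rng.standard_normal(3)
            dd /= np.linalg.norm(dd)
            q = p + dd * step_um / voxel_size
            if inside(q):
                p, d = q, dd
                points.append(p.copy())
                placed = True
                break
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
        if not placed:
            break
    return points


def generate_phantom(params: PhantomParams) -> PhantomTruth:
    """Generate one phantom scan plus ground-truth labels.

    Deterministic: identical params (including seed) give voxel-identical
    output. Raises :class:`PhantomPlacementError` if a gland cannot be placed
    inside the endometrium after a bounded number of attempts.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    vs = np.asarray(params.voxel_size, dtype=float)
    nz, ny, nx = shape

    labels = np.zeros(shape, dtype=np.uint8)

    # Myometrial shell: a bright frame inside the y/x borders (the scan is a
    # crop of the endometrium with the muscle wall at its edges).
    myo = np.zeros(shape, dtype=bool)
    if params.myometrium_present:
        ty = max(1, int(round(params.myometrium_thickness / vs[1])))
        tx = max(1, int(round(params.myometrium_thickness / vs[2])))
        myo[:, :ty, :] = myo[:, -ty:, :] = True
        myo[:, :, :tx] = myo[:, :, -tx:] = True

    # Lumen: central elliptical channel running through every slice.
    lumen = np.zeros(shape, dtype=bool)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    if params.lumen_present:
        yy, xx = np.ogrid[:ny, :nx]
        ry = params.lumen_halfwidth / vs[1]
        rx = params.lumen_halfwidth / vs[2]
        ell = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        lumen[:] = ell[None]

    # Endometrium available to glands: away from the myometrium and lumen by
    # a cage-sized margin so every cage fits.
    margin = params.cage_thickness + params.lumen_gap

    def inside_endometrium(q: np.ndarray, radius_um: float) -> bool:
        if np.any(q < 0) or np.any(q > np.array(shape) - 1):
            return False
        need = radius_um + params.cage_thickness
        zu, yu, xu = q * vs
        if params.myometrium_present:
            if yu < params.myometrium_thickness + need:
                return False
            if yu > (ny - 1) * vs[1] - params.myometrium_thickness - need:
                return False
            if xu < params.myometrium_thickness + need:
                return False
            if xu > (nx - 1) * vs[2] - params.myometrium_thickness - need:
                return False
        if params.lumen_present:
            dy = (q[1] - cy) * vs[1]
            dx = (q[2] - cx) * vs[2]
            if np.hypot(dy, dx) < params.lumen_halfwidth + params.lumen_gap + radius_um:
                return False
        return True

    glands = np.zeros(shape, dtype=bool)
    for _ in range(params.n_glands):
        placed = False
        for _attempt in range(40):
            radius = _uniform(rng, params.gland_radius)
            length = _uniform(rng, params.gland_length)
            theta = rng.uniform(0, 2 * np.pi)
            z0 = rng.uniform(0.15 * nz, 0.85 * nz)
            if params.lumen_present:
                r0 = params.lumen_halfwidth + params.lumen_gap + radius + 0.5
                start = np.array([
                    z0,
                    cy + r0 * np.sin(theta) / vs[1],
                    cx + r0 * np.cos(theta) / vs[2],
                ])
                direction = np.array([0.1, np.sin(theta), np.cos(theta)])
            else:
                start = np.array([
                    z0,
                    rng.uniform(0.2 * ny, 0.8 * ny),
                    rng.uniform(0.2 * nx, 0.8 * nx),
                ])
                direction = rng.standard_normal(3)
            if not inside_endometrium(start, radius):
                continue
            n_steps = max(2, int(round(length / params.centerline_step)))
            pts = _grow_centerline(
                rng, start, direction, n_steps, params.centerline_step,
                params.centerline_curvature, vs,
                lambda q, r=radius: inside_endometrium(q, r),
            )
            if len(pts) < max(3, n_steps // 3):
                continue
            cand = np.zeros(shape, dtype=bool)
            for p in pts:
                _stamp_ball(cand, p, radius, vs)
            # Terminal lobes: spheres at the tip and along the distal third.
            n_lobes = int(rng.integers(params.lobes_per_gland[0],
                                       params.lobes_per_gland[1] + 1))
            lobe_anchor_ids = [len(pts) - 1] + list(
                rng.integers(2 * len(pts) // 3, len(pts), size=max(0, n_lobes - 1))
            )
            for i in lobe_anchor_ids[:n_lobes]:
                lr = _uniform(rng, params.lobe_radius)
                if inside_endometrium(pts[i], lr):
                    _stamp_ball(cand, pts[i], lr, vs)
            cand &= ~myo
            cand &= ~lumen
            if not cand.any():
                continue
            glands |= cand
            placed = True
            break
        if not placed:
            raise PhantomPlacementError(
                "could not place a gland inside the endometrium; shrink the "
                "glands or enlarge the volume"
            )

    # Cage: shell of cage_thickness around the glands, fragmented by deleting
    # contiguous surface patches until only cage_continuity of it remains.
    cage = np.zeros(shape, dtype=bool)
    cage_gaps = np.zeros(shape, dtype=bool)
    if glands.any():
        dist = ndi.distance_transform_edt(~glands, sampling=vs)
        cage = (dist <= params.cage_thickness) & ~glands & ~lumen & ~myo
        # The fragmentation field is always drawn so that phantoms at the
        # same seed differ only where cage patches are actually deleted.
        # Deleted patches become collagen-poor gaps: dim voxels through
        # which the hole outline is incomplete, the documented reason
        # fragmented (diestrus) cages defeat negative-space segmentation.
        blob = ndi.gaussian_filter(rng.standard_normal(shape), sigma=5.0 / vs)
        if params.cage_continuity < 1.0 and cage.any():
            cut = np.quantile(blob[cage], params.cage_continuity)
            cage_gaps = cage & (blob > cut)
            cage &= blob <= cut

    labels[cage] = CAGE
    labels[glands] = GLAND
    labels[lumen] = LUMEN
    labels[myo] = MYOMETRIUM

    # Intensities (pre-noise): stroma and myometrium carry speckled fibrillar
    # texture; the cage is exactly cage_ratio * stroma_mean; interiors are
    # nearly dark (5% of stroma, well under the stroma_mean/4 contract).
    scale_vox = params.stroma_texture_scale / vs
    speckle = _speckle(shape, scale_vox, rng)
    vol = params.stroma_mean * speckle
    vol[cage_gaps] = params.cage_gap_level * params.stroma_mean
    vol[labels == CAGE] = params.cage_ratio * params.stroma_mean
    dark = params.stroma_mean * 0.05
    vol[labels == GLAND] = dark
    vol[labels == LUMEN] = dark
    vol[labels == MYOMETRIUM] = (
        params.myometrium_multiplier * params.stroma_mean
        * speckle[labels == MYOMETRIUM]
    )

    if not params.compensated and params.attenuation > 0:
        depth = np.arange(nz, dtype=float) * vs[0]
        vol *= np.exp(-params.attenuation * depth)[:, None, None]

    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=shape)
    top = 2**params.bit_depth - 1
    vol = np.clip(np.rint(vol), 0, top)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    scan = VolumeScan(
        voxels=vol.astype(dtype),
        voxel_size=params.voxel_size,
        bit_depth=params.bit_depth,
        channel="shg",
    )
    lab = LabelVolume(
        labels=labels, class_map=dict(PHANTOM_CLASS_MAP),
        voxel_size=params.voxel_size,
    )
    return PhantomTruth(scan=scan, labels=lab, params=params)


def truth_negative_space(truth: PhantomTruth) -> LabelVolume:
    """Binary ground-truth segmentation target: gland interiors plus lumen.

    Cage, stroma and myometrium are excluded — the target is the SHG-dark
    negative impression up to the collagen outline.
    """
    fg = (truth.labels.labels == GLAND) | (truth.labels.labels == LUMEN)
    return LabelVolume(
        labels=fg.astype(np.uint8),
        class_map={0: "background", 1: "negative_space"},
        voxel_size=truth.labels.voxel_size,
    )


def params_to_dict(params: PhantomParams) -> dict:
    """YAML/JSON-serializable copy of the parameters."""
    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def params_from_dict(d: dict) -> PhantomParams:
    base = PhantomParams()
    kwargs = {}
    for k, v in d.items():
        cur = getattr(base, k)  # raises on unknown keys
        kwargs[k] = tuple(v) if isinstance(cur, tuple) else v
    return replace(base, **kwargs)
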