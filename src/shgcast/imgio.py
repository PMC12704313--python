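"""Reading, writing and bit-depth handling for multi-page TIFF image stacks.

Every volume in this package is a ``(z, y, x)``-ordered grid with 0-based
indices and half-open ranges. Physical voxel sizes are carried explicitly in
micrometres, in the same ``(z, y, x)`` order, because all downstream
measurements (thicknesses, volumes, Hausdorff distances in physical units)
are metric. A scan without a known voxel size is an error, never a silent
default.

Voxel-size precedence on read: explicit override > TIFF (ImageJ) metadata >
sidecar YAML (``<file>.yaml``) > error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VolumeScan",
    "LabelVolume",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "to_8bit",
]


@dataclass
class VolumeScan:
    """A single-channel 3D intensity grid with physical voxel metadata.

    Attributes
    ----------
    voxels : numpy.ndarray
        Non-negative intensities, shape ``(n_slices, height, width)``.
    voxel_size : tuple of float
        ``(z, y, x)`` spacing in micrometres.
    bit_depth : int
        8 or 16; every intensity must be ``<= 2**bit_depth - 1``.
    channel : str
        One of ``{"shg", "immuno", "other"}``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    bit_depth: int = 16
    channel: str = "shg"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) grid with >= 1 slice")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive (z, y, x) values in um")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.voxels.size and (
            self.voxels.min() < 0 or self.voxels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError("intensities must lie in [0, 2**bit_depth - 1]")
        if self.channel not in {"shg", "immuno", "other"}:
            raise ValueError(f"unknown channel tag {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """Integer class grid co-registered with a :class:`VolumeScan`.

    ``class_map`` names every label value that occurs; by convention 0 is
    background/stroma and 1 is the gland+lumen negative space. Phantom ground
    truth additionally uses 2 = cage, 3 = lumen, 4 = myometrium.
    """

    labels: np.ndarray
    class_map: dict[int, str] = field(
        default_factory=lambda: {0: "background", 1: "negative_space"}
    )
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (z, y, x) grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"label values {sorted(missing)} missing from class_map")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, value: int = 1) -> np.ndarray:
        """Boolean mask of one class."""
        return self.labels == value


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    z = meta.get("spacing")
    page = tif.pages[0]
    yx = []
    for tag_name in ("YResolution", "XResolution"):
        tag = page.tags.get(tag_name)
        if tag is None:
            return None
        num, den = tag.value
        if num == 0:
            return None
        yx.append(den / num)  # pixels-per-um resolution -> um-per-pixel
    if z is None:
        return None
    return (float(z), float(yx[0]), float(yx[1]))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel: str = "shg",
) -> VolumeScan:
    """Read a single-channel multi-page TIFF as a :class:`VolumeScan`.

    Parameters
    ----------
    path : path-like
        Grayscale 8- or 16-bit multi-page TIFF.
    voxel_size : tuple, optional
        Explicit ``(z, y, x)`` spacing in um. Takes precedence over any
        metadata. If neither an override, TIFF metadata nor a sidecar YAML
        (``<file>.yaml`` with a ``voxel_size`` key) supplies a spacing, a
        ``ValueError`` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path} has {page.samplesperpixel} samples per pixel; "
                "expected a single-channel grayscale stack"
            )
        data = tif.asarray()
        meta_vs = _voxel_size_from_tiff(tif)
    if data.ndim == 2:
        data = data[None]
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported sample format {data.dtype}; expected uint8/uint16")

    vs = voxel_size
    if vs is None:
        vs = meta_vs
    if vs is None and _sidecar_path(path).exists():
        with open(_sidecar_path(path)) as fh:
            side = yaml.safe_load(fh)
        vs = tuple(side["voxel_size"])
    if vs is None:
        raise ValueError(
            f"no voxel size for {path}: pass voxel_size=, or provide TIFF metadata "
            "or a sidecar YAML"
        )
    return VolumeScan(voxels=data, voxel_size=vs, bit_depth=bit_depth, channel=channel)


def write_stack(scan: VolumeScan, path: str | Path) -> Path:
    """Write a scan as an ImageJ-style multi-page TIFF with voxel metadata."""
    path = Path(path)
    dtype = np.uint8 if scan.bit_depth == 8 else np.uint16
    z, y, x = scan.voxel_size
    tifffile.imwrite(
        path,
        scan.voxels.astype(dtype),
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )
    return path


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label map as an 8-bit TIFF.

    Binary maps (classes subset of {0, 1}) are stored as 0/255, mirroring the
    common export convention where any nonzero value is foreground after
    16-to-8-bit conversion. Multi-class maps store raw class values.
    """
    path = Path(path)
    values = labels.labels
    if set(np.unique(values).tolist()) <= {0, 1}:
        values = (values * 255).astype(np.uint8)
    else:
        if values.max() > 255:
            raise ValueError("label values exceed 8-bit range")
        values = values.astype(np.uint8)
    z, y, x = labels.voxel_size
    tifffile.imwrite(
        path,
        values,
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )
    return path


def read_labels(
    path: str | Path,
    class_map: dict[int, str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> LabelVolume:
    """Read a label map written by :func:`write_labels`.

    A 0/255 file is interpreted as binary {0, 1}; any other value set is kept
    verbatim (with a generated class_map when none is given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_vs = _voxel_size_from_tiff(tif)
    if data.ndim == 2:
        data = data[None]
    vs = voxel_size or meta_vs or (1.0, 1.0, 1.0)
    values = set(np.unique(data).tolist())
    if values <= {0, 255}:
        data = (data > 0).astype(np.uint8)
        cmap = class_map or {0: "background", 1: "negative_space"}
    else:
        data = data.astype(np.uint8)
        cmap = class_map or {int(v): f"class_{int(v)}" for v in sorted(values)}
    return LabelVolume(labels=data, class_map=cmap, voxel_size=vs)


def to_8bit(scan: VolumeScan, policy: str = "fixed_range") -> VolumeScan:
    """Convert a 16-bit scan to 8 bits.

    ``fixed_range`` maps [0, 65535] -> [0, 255] linearly with round-half-up;
    ``min_max`` maps [min, max] -> [0, 255] (a constant volume maps to 0).
    An already-8-bit scan is returned unchanged with a warning.
    """
    if scan.bit_depth == 8:
        warnings.warn("scan is already 8-bit; returning unchanged", stacklevel=2)
        return scan
    v = scan.voxels.astype(np.float64)
    if policy == "fixed_range":
        out = np.floor(v * 255.0 / 65535.0 + 0.5)
    elif policy == "min_max":
        lo, hi = v.min(), v.max()
        if hi == lo:
            out = np.zeros_like(v)
        else:
            out = np.floor((v - lo) * 255.0 / (hi - lo) + 0.5)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return VolumeScan(
        voxels=out.astype(np.uint8),
        voxel_size=scan.voxel_size,
        bit_depth=8,
        channel=scan.channel,
    )
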