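"""Two-phase learned segmentation workflow on sparse slice annotations.

The workflow mirrors how dense 3D training labels are assembled from sparse
manual work: (1) annotate every k-th slice of each scan; (2) train a 2D
slice model on those annotations; (3) let the slice model predict the
remaining slices, keeping manual slices verbatim, to build dense 3D
pseudo-label volumes; (4) train a 3D model on the pseudo-labeled volumes;
(5) run the 3D model on held-out scans with overlapping sliding windows and
mean-blended probabilities. Scans are split into disjoint train /
validation / test sets at the scan level, and model snapshots are selected
by validation Dice.

The per-pixel learners here are random forests over multiscale Gaussian
derivative features (smoothed intensity, gradient magnitude and Laplacian
at several scales) — the classic trainable-segmentation recipe, which runs
deterministically on a single CPU. "Epochs" are rounds of tree growth: each
epoch adds ``trees_per_epoch`` trees and records validation Dice, and the
returned model is truncated to the best-scoring epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .casting import UNLABELED
from .imgio import LabelVolume, VolumeScan
from .metrics import aggregate_metrics

__all__ = [
    "SliceSample",
    "TrainConfig",
    "ModelBundle",
    "sample_annotation_slices",
    "sparse_manual_labels",
    "train_slice_model",
    "build_pseudo_labels",
    "train_volume_model",
    "infer_volume",
    "run_workflow",
]


@dataclass
class SliceSample:
    """One 2D slice with an optional mask and its provenance."""

    image: np.ndarray
    mask: np.ndarray | None
    provenance: str  # {"manual", "pseudo", "unlabeled"}
    scan_id: str = ""
    slice_index: int = -1

    def __post_init__(self):
        if self.provenance not in {"manual", "pseudo", "unlabeled"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "manual" and self.mask is None:
            raise ValueError("manual samples must carry a mask")
        if self.mask is not None and self.mask.shape != self.image.shape:
            raise ValueError("mask shape must equal image shape")


@dataclass
class TrainConfig:
    """Configuration for the forest pixel classifiers.

    ``arch`` selects dimensionality: ``rf2d`` (per-slice features) or
    ``rf3d`` (volumetric features). ``patch`` is the sliding-window size
    used at 3D inference. ``epochs`` tree-growth rounds of
    ``trees_per_epoch`` trees each; the snapshot with the best validation
    Dice is kept. ``feature_sigmas`` are the Gaussian scales (voxels).
    ``max_samples_per_item`` caps the pixels drawn from each training slice
    or volume (class-balanced where possible). Images are z-scored per item
    before feature extraction. Probabilities are binarized at
    ``binarize_at``; a tie at exactly 0.5 is foreground.
    """

    arch: str = "rf2d"
    patch: tuple[int, ...] = (32, 64, 64)
    epochs: int = 5
    trees_per_epoch: int = 10
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    max_samples_per_item: int = 6000
    max_depth: int | None = 12
    normalize: str = "zscore_per_item"
    binarize_at: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.arch not in {"rf2d", "rf3d"}:
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ModelBundle:
    """A trained classifier, its config, and the per-epoch training log."""

    clf: RandomForestClassifier
    config: TrainConfig
    ndim: int
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    def predict_proba_image(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map for one image (2D) or volume (3D)."""
        if image.ndim != self.ndim:
            raise ValueError(f"model expects {self.ndim}D input, got {image.ndim}D")
        feats = _features(_normalize(image), self.config.feature_sigmas)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.clf.predict_proba(flat)
        fg_col = list(self.clf.classes_).index(1) if 1 in self.clf.classes_ else None
        if fg_col is None:
            return np.zeros(image.shape, dtype=np.float64)
        return proba[:, fg_col].reshape(image.shape)


def sample_annotation_slices(n_slices: int, stride: int, offset: int = 0) -> list[int]:
    """Ascending indices {offset, offset+stride, ...} below ``n_slices``."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0 <= offset < stride:
        raise ValueError("offset must satisfy 0 <= offset < stride")
    return list(range(offset, n_slices, stride))


def sparse_manual_labels(
    dense: LabelVolume, slice_indices: list[int]
) -> LabelVolume:
    """Keep the given slices of a dense mask; mark the rest UNLABELED."""
    lab = np.full(dense.shape, UNLABELED, dtype=np.uint8)
    for z in slice_indices:
        lab[z] = dense.labels[z] > 0
    cmap = {0: "background", 1: "negative_space", UNLABELED: "unlabeled"}
    return LabelVolume(labels=lab, class_map=cmap, voxel_size=dense.voxel_size)


def _normalize(image: np.ndarray) -> np.ndarray:
    img = image.astype(np.float64)
    sd = img.std()
    return (img - img.mean()) / sd if sd > 0 else img - img.mean()


def _features(image: np.ndarray, sigmas) -> np.ndarray:
    """Multiscale Gaussian derivative features, shape ``image.shape + (F,)``."""
    chans = [image]
    for s in sigmas:
        chans.append(ndi.gaussian_filter(image, sigma=s))
        chans.append(ndi.gaussian_gradient_magnitude(image, sigma=s))
        chans.append(ndi.gaussian_laplace(image, sigma=s))
    return np.stack(chans, axis=-1)


def _sample_pixels(
    feats: np.ndarray, mask: np.ndarray, cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced pixel subsample from one labeled item."""
    flat_x = feats.reshape(-1, feats.shape[-1])
    flat_y = (mask.ravel() > 0).astype(np.int8)
    idx_fg = np.flatnonzero(flat_y == 1)
    idx_bg = np.flatnonzero(flat_y == 0)
    half = cap // 2
    take_fg = min(len(idx_fg), half)
    take_bg = min(len(idx_bg), cap - take_fg)
    sel = []
    if take_fg:
        sel.append(rng.choice(idx_fg, size=take_fg, replace=False))
    if take_bg:
        sel.append(rng.choice(idx_bg, size=take_bg, replace=False))
    sel = np.concatenate(sel) if sel else np.empty(0, dtype=int)
    return flat_x[sel], flat_y[sel]


def _dice(pred: np.ndarray, ref: np.ndarray) -> float:
    p, r = pred > 0, ref > 0
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(p & r) / denom


def _train_forest(
    train_items: list[tuple[np.ndarray, np.ndarray]],
    val_items: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    ndim: int,
) -> ModelBundle:
    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for image, mask in train_items:
        feats = _features(_normalize(image), config.feature_sigmas)
        x, y = _sample_pixels(feats, mask, config.max_samples_per_item, rng)
        xs.append(x)
        ys.append(y)
    X = np.concatenate(xs)
    Y = np.concatenate(ys)
    if len(X) == 0:
        raise ValueError("empty training set")
    degenerate = len(np.unique(Y)) < 2

    val_feats = [
        (_features(_normalize(img), config.feature_sigmas), msk)
        for img, msk in val_items
    ]

    # class balance is handled by _sample_pixels, not by class_weight
    # (reweighting interacts badly with warm_start tree growth)
    clf = RandomForestClassifier(
        n_estimators=0,
        warm_start=True,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    log: list[dict] = []
    best_epoch, best_dsc = 1, -1.0
    for epoch in range(1, config.epochs + 1):
        clf.n_estimators = epoch * config.trees_per_epoch
        clf.fit(X, Y)
        train_acc = float(clf.score(X, Y))
        val_dscs = []
        for feats, msk in val_feats:
            flat = feats.reshape(-1, feats.shape[-1])
            if 1 in clf.classes_:
                col = list(clf.classes_).index(1)
                proba = clf.predict_proba(flat)[:, col]
            else:
                proba = np.zeros(len(flat))
            pred = proba.reshape(msk.shape) >= config.binarize_at
            val_dscs.append(_dice(pred, msk))
        val_dsc = float(np.mean(val_dscs)) if val_dscs else float("nan")
        entry = {
            "epoch": epoch,
            "n_trees": clf.n_estimators,
            "train_accuracy": train_acc,
            "val_dsc": val_dsc,
        }
        if degenerate:
            entry["degenerate_labels"] = True
        log.append(entry)
        if val_dscs and val_dsc > best_dsc:
            best_dsc, best_epoch = val_dsc, epoch
    # snapshot: truncate the forest to the best epoch's trees
    keep = best_epoch * config.trees_per_epoch
    clf.estimators_ = clf.estimators_[:keep]
    clf.n_estimators = keep
    return ModelBundle(clf=clf, config=config, ndim=ndim,
                       training_log=log, best_epoch=best_epoch)


def train_slice_model(
    samples: list[SliceSample],
    val_samples: list[SliceSample],
    config: TrainConfig | None = None,
) -> ModelBundle:
    """Train the 2D slice model on manually annotated slices.

    Validation samples must come from scans disjoint from the training
    scans; the best snapshot by mean validation Dice is returned.
    """
    config = config or TrainConfig(arch="rf2d")
    if config.arch != "rf2d":
        config = replace(config, arch="rf2d")
    labeled = [(s.image, s.mask) for s in samples if s.mask is not None]
    if not labeled:
        raise ValueError("empty training set: no labeled slices")
    overlap = {s.scan_id for s in samples} & {s.scan_id for s in val_samples}
    if overlap and overlap != {""}:
        raise ValueError(f"validation scans overlap training scans: {overlap}")
    val = [(s.image, s.mask) for s in val_samples if s.mask is not None]
    return _train_forest(labeled, val, config, ndim=2)


def build_pseudo_labels(
    model, scan: VolumeScan, manual: LabelVolume
) -> LabelVolume:
    """Dense labels: model predictions everywhere, manual slices verbatim.

    ``manual`` is a sparse label volume (UNLABELED on untraced slices). The
    manual-override rule is exact: annotated slices are copied, never
    predicted. ``model`` needs a ``predict_proba_image(image) -> proba``
    method and a ``config.binarize_at`` threshold (ties go to foreground).
    """
    if manual.shape != scan.shape:
        raise ValueError("manual labels and scan shapes differ")
    thr = model.config.binarize_at
    out = np.zeros(scan.shape, dtype=np.uint8)
    provenance = []
    for z in range(scan.shape[0]):
        if np.any(manual.labels[z] == UNLABELED):
            proba = model.predict_proba_image(scan.voxels[z].astype(np.float64))
            out[z] = proba >= thr
            provenance.append("pseudo")
        else:
            out[z] = manual.labels[z] > 0
            provenance.append("manual")
    return LabelVolume(labels=out, class_map={0: "background", 1: "negative_space"},
                       voxel_size=scan.voxel_size)


def train_volume_model(
    pairs: list[tuple[VolumeScan, LabelVolume]],
    val_pairs: list[tuple[VolumeScan, LabelVolume]],
    config: TrainConfig | None = None,
) -> ModelBundle:
    """Train the 3D model on (scan, dense-label) pairs."""
    config = config or TrainConfig(arch="rf3d")
    if config.arch != "rf3d":
        config = replace(config, arch="rf3d")
    if not pairs:
        raise ValueError("empty training set")
    for scan, _lab in pairs:
        if any(p > s for p, s in zip(config.patch, scan.shape)):
            raise ValueError(
                f"patch {config.patch} exceeds training volume {scan.shape}"
            )
    items = [(s.voxels.astype(np.float64), l.labels) for s, l in pairs]
    val = [(s.voxels.astype(np.float64), l.labels) for s, l in val_pairs]
    return _train_forest(items, val, config, ndim=3)


def _window_starts(extent: int, window: int, step: int) -> list[int]:
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window, step))
    starts.append(extent - window)
    return starts


def infer_volume(model: ModelBundle, scan: VolumeScan) -> LabelVolume:
    """Apply a trained model to a whole scan.

    2D models run slice-wise. 3D models run in overlapping sliding windows
    (50% step, i.e. >= 25% overlap per axis) whose probabilities are
    mean-blended before binarization at the configured threshold; a scan
    smaller than one window falls back to a single edge-padded window.
    """
    vol = scan.voxels.astype(np.float64)
    thr = model.config.binarize_at
    if model.ndim == 2:
        out = np.zeros(scan.shape, dtype=np.uint8)
        for z in range(scan.shape[0]):
            out[z] = model.predict_proba_image(vol[z]) >= thr
        return LabelVolume(labels=out, class_map={0: "background", 1: "negative_space"},
                           voxel_size=scan.voxel_size)

    # Normalization and feature extraction are per scan (the "item"), shared
    # by every window: window-local statistics would shift the features and
    # make predictions depend on the tiling.
    patch = tuple(model.config.patch)
    pads = [max(0, p - s) for p, s in zip(patch, scan.shape)]
    padded = np.pad(vol, [(0, p) for p in pads], mode="edge") if any(pads) else vol
    feats = _features(_normalize(padded), model.config.feature_sigmas)
    if 1 in model.clf.classes_:
        fg_col = list(model.clf.classes_).index(1)
    else:
        fg_col = None
    acc = np.zeros(padded.shape, dtype=np.float64)
    weight = np.zeros(padded.shape, dtype=np.float64)
    steps = [max(1, p // 2) for p in patch]
    for z0 in _window_starts(padded.shape[0], patch[0], steps[0]):
        for y0 in _window_starts(padded.shape[1], patch[1], steps[1]):
            for x0 in _window_starts(padded.shape[2], patch[2], steps[2]):
                sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                      slice(x0, x0 + patch[2]))
                win = feats[sl].reshape(-1, feats.shape[-1])
                if fg_col is None:
                    proba_win = np.zeros(len(win))
                else:
                    proba_win = model.clf.predict_proba(win)[:, fg_col]
                acc[sl] += proba_win.reshape(patch)
                weight[sl] += 1.0
    proba = acc / weight
    out = (proba >= thr)[: scan.shape[0], : scan.shape[1], : scan.shape[2]]
    return LabelVolume(labels=out.astype(np.uint8),
                       class_map={0: "background", 1: "negative_space"},
                       voxel_size=scan.voxel_size)


def run_workflow(
    scans: list[VolumeScan],
    truths: list[LabelVolume],
    split: dict[str, list[int]],
    stride: int = 15,
    config2d: TrainConfig | None = None,
    config3d: TrainConfig | None = None,
) -> dict:
    """End-to-end sparse-annotation workflow with a scan-level split.

    ``truths`` are dense binary reference masks; on training and validation
    scans they play the role of the manual annotator (only every
    ``stride``-th slice of them is ever shown to the 2D model). The report
    carries three assessment axes, each with all five segmentation metrics:

    * ``slice_model_vs_manual`` — 2D model against manual (reference)
      slices of the test scans, per-slice mean;
    * ``volume_model_vs_pseudo`` — 3D model against the pseudo-label
      volumes of the test scans;
    * ``slice_model_vs_truth`` / ``volume_model_vs_truth`` — both models
      against the dense ground truth of the test scans (available here
      because the inputs are synthetic).
    """
    ids = [i for part in split.values() for i in part]
    if len(set(ids)) != len(ids):
        raise ValueError("split parts overlap")
    if set(ids) - set(range(len(scans))):
        raise ValueError("split references unknown scan indices")
    train_ids, val_ids = split["train"], split["val"]
    test_ids = split["test"]
    config2d = config2d or TrainConfig(arch="rf2d")
    # a volume is ~100x the size of a slice, so the 3D learner gets a
    # proportionally larger per-item pixel budget by default
    config3d = config3d or TrainConfig(arch="rf3d", seed=config2d.seed + 1,
                                       max_samples_per_item=24000)

    def manual_sparse(i: int) -> LabelVolume:
        zs = sample_annotation_slices(scans[i].shape[0], stride)
        return sparse_manual_labels(truths[i], zs)

    def manual_slices(i: int, provenance="manual") -> list[SliceSample]:
        zs = sample_annotation_slices(scans[i].shape[0], stride)
        return [
            SliceSample(
                image=scans[i].voxels[z].astype(np.float64),
                mask=(truths[i].labels[z] > 0).astype(np.uint8),
                provenance=provenance, scan_id=str(i), slice_index=z,
            )
            for z in zs
        ]

    train_samples = [s for i in train_ids for s in manual_slices(i)]
    val_samples = [s for i in val_ids for s in manual_slices(i)]
    model2d = train_slice_model(train_samples, val_samples, config2d)

    pseudo = {
        i: build_pseudo_labels(model2d, scans[i], manual_sparse(i))
        for i in train_ids + val_ids + test_ids
    }
    model3d = train_volume_model(
        [(scans[i], pseudo[i]) for i in train_ids],
        [(scans[i], pseudo[i]) for i in val_ids],
        config3d,
    )

    pred2d = {i: infer_volume(model2d, scans[i]) for i in test_ids}
    pred3d = {i: infer_volume(model3d, scans[i]) for i in test_ids}

    slice_pairs = []
    for i in test_ids:
        for z in sample_annotation_slices(scans[i].shape[0], stride):
            slice_pairs.append((pred2d[i].labels[z], truths[i].labels[z] > 0))
    report = {
        "split": {k: list(v) for k, v in split.items()},
        "stride": stride,
        "model2d_log": model2d.training_log,
        "model3d_log": model3d.training_log,
        "slice_model_vs_manual": aggregate_metrics(slice_pairs).as_dict(),
        "volume_model_vs_pseudo": aggregate_metrics(
            [(pred3d[i].labels, pseudo[i].labels) for i in test_ids]
        ).as_dict(),
        "slice_model_vs_truth": aggregate_metrics(
            [(pred2d[i].labels, truths[i].labels) for i in test_ids]
        ).as_dict(),
        "volume_model_vs_truth": aggregate_metrics(
            [(pred3d[i].labels, truths[i].labels) for i in test_ids]
        ).as_dict(),
    }
    return report
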