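"""Contour rasterization, sparse-slice interpolation, classical casting
and single-gland isolation."""

import numpy as np
import pytest

from conftest import small_params
from shgcast.casting import (
    UNLABELED,
    AnnotationSet,
    CastParams,
    ContourAnnotation,
    NoMoldError,
    interpolate_sparse_masks,
    isolate_glands,
    rasterize_contours,
    segment_negative_space_classical,
)
from shgcast.imgio import LabelVolume, VolumeScan
from shgcast.metrics import evaluate_masks
from shgcast.phantom import generate_phantom, stage_preset, truth_negative_space


def point_in_polygon_oracle(y, x, verts, eps=1e-9):
    """Even-odd crossing-number test plus on-segment boundary check."""
    n = len(verts)
    on_boundary = False
    inside = False
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        # boundary: point on segment
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < eps:
            if min(x1, x2) - eps <= x <= max(x1, x2) + eps and \
               min(y1, y2) - eps <= y <= max(y1, y2) + eps:
                on_boundary = True
        # even-odd ray cast along +x
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside or on_boundary


def circle_contours(center, radius, slices, n_verts=72):
    theta = np.linspace(0, 2 * np.pi, n_verts, endpoint=False)
    verts = tuple((center[0] + radius * np.sin(t),
                   center[1] + radius * np.cos(t)) for t in theta)
    return [ContourAnnotation(slice_index=z, vertices=verts) for z in slices]


def test_square_contour_fills_inclusive_interior():
    ann = AnnotationSet(scan_id="s", stride=1, contours=[
        ContourAnnotation(0, ((2, 2), (2, 6), (6, 6), (6, 2)))])
    out = rasterize_contours(ann, (2, 10, 10))
    assert int((out.labels[0] == 1).sum()) == 25
    assert np.all(out.labels[1] == UNLABELED)


def test_empty_annotation_set_all_unlabeled():
    out = rasterize_contours(AnnotationSet("s", stride=3), (4, 8, 8))
    assert np.all(out.labels == UNLABELED)


def test_triangle_matches_point_in_polygon_oracle():
    verts = ((0, 0), (0, 4), (4, 0))
    ann = AnnotationSet("s", 1, [ContourAnnotation(0, verts)])
    got = rasterize_contours(ann, (1, 6, 6)).labels[0] == 1
    expected = np.array([
        [point_in_polygon_oracle(y, x, verts) for x in range(6)]
        for y in range(6)
    ])
    assert np.array_equal(got, expected)


def test_invalid_contours_rejected():
    with pytest.raises(ValueError, match="3 vertices"):
        ContourAnnotation(0, ((0, 0), (1, 1)))
    bowtie = ContourAnnotation(0, ((0, 0), (4, 4), (0, 4), (4, 0)))
    with pytest.raises(ValueError, match="self-intersecting"):
        rasterize_contours(AnnotationSet("s", 1, [bowtie]), (1, 6, 6))
    outside = ContourAnnotation(0, ((0, 0), (0, 20), (20, 20)))
    with pytest.raises(ValueError, match="outside"):
        rasterize_contours(AnnotationSet("s", 1, [outside]), (1, 6, 6))
    with pytest.raises(ValueError, match="slice"):
        rasterize_contours(
            AnnotationSet("s", 1, [ContourAnnotation(9, ((0, 0), (0, 3), (3, 0)))]),
            (1, 6, 6))


def test_interpolation_constant_disk_passes_through():
    ann = AnnotationSet("s", 3, circle_contours((12, 12), 6.0, [0, 3]))
    sparse = rasterize_contours(ann, (4, 25, 25))
    dense = interpolate_sparse_masks(sparse, stride=3)
    for z in (1, 2):
        assert np.array_equal(dense.labels[z], dense.labels[0])
    assert np.array_equal(dense.labels[0], (sparse.labels[0] == 1).astype(np.uint8))


def test_interpolation_tapers_linearly():
    ann = AnnotationSet("s", 4, circle_contours((20, 20), 4.0, [0])
                        + circle_contours((20, 20), 8.0, [4]))
    sparse = rasterize_contours(ann, (5, 41, 41))
    dense = interpolate_sparse_masks(sparse, stride=4)
    mid = dense.labels[2]
    radius = np.sqrt(mid.sum() / np.pi)
    assert radius == pytest.approx(6.0, abs=1.0)


def test_interpolation_shrinks_toward_empty_slice():
    ann = AnnotationSet("s", 3, circle_contours((12, 12), 8.0, [0]))
    sparse = rasterize_contours(ann, (4, 25, 25))
    sparse.labels[3] = 0  # annotated empty slice
    dense = interpolate_sparse_masks(sparse, stride=3)
    areas = [int(dense.labels[z].sum()) for z in range(4)]
    assert areas[0] > 0 and areas[3] == 0
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_interpolation_requires_annotations():
    sparse = LabelVolume(np.full((3, 5, 5), UNLABELED, np.uint8),
                         class_map={UNLABELED: "unlabeled"})
    with pytest.raises(ValueError, match="no annotated"):
        interpolate_sparse_masks(sparse)


def test_cylinder_reconstruction_every_third_slice():
    nz = 31
    contours = circle_contours((20, 20), 10.0, range(nz))
    reference = rasterize_contours(
        AnnotationSet("ref", 1, contours), (nz, 41, 41)).labels == 1
    sparse = rasterize_contours(
        AnnotationSet("s", 3, [c for c in contours if c.slice_index % 3 == 0]),
        (nz, 41, 41))
    dense = interpolate_sparse_masks(sparse, stride=3)
    m = evaluate_masks(dense.labels, reference)
    assert m.dsc >= 0.98


def test_classical_casting_on_estrus_phantom():
    truth = generate_phantom(stage_preset("estrus", seed=11))
    seg = segment_negative_space_classical(truth.scan, CastParams())
    m = evaluate_masks(seg, truth_negative_space(truth))
    assert m.dsc >= 0.95


def test_classical_casting_is_deterministic():
    truth = generate_phantom(small_params())
    a = segment_negative_space_classical(truth.scan)
    b = segment_negative_space_classical(truth.scan)
    assert np.array_equal(a.labels, b.labels)


def test_classical_casting_idempotent_on_binary_volume():
    truth = generate_phantom(small_params())
    params = CastParams(threshold=500.0)
    first = segment_negative_space_classical(truth.scan, params)
    relabeled = np.where(first.labels > 0, 0, 60000).astype(np.uint16)
    again = segment_negative_space_classical(
        VolumeScan(relabeled, truth.scan.voxel_size), params)
    assert np.array_equal(again.labels, first.labels)


def test_uniformly_bright_volume_gives_empty_cast():
    scan = VolumeScan(np.full((6, 16, 16), 60000, np.uint16), (1, 1, 1))
    out = segment_negative_space_classical(scan, CastParams(threshold=1000.0))
    assert not out.labels.any()
    with pytest.raises(NoMoldError):
        segment_negative_space_classical(scan, CastParams(threshold=65535.0))


def test_classical_estrus_beats_diestrus_at_matched_seed():
    for seed in (0, 1):
        d_est = evaluate_masks(
            segment_negative_space_classical(
                generate_phantom(stage_preset("estrus", seed=seed)).scan),
            truth_negative_space(generate_phantom(stage_preset("estrus", seed=seed)))).dsc
        d_die = evaluate_masks(
            segment_negative_space_classical(
                generate_phantom(stage_preset("diestrus", seed=seed)).scan),
            truth_negative_space(generate_phantom(stage_preset("diestrus", seed=seed)))).dsc
        assert d_est > d_die


def two_tubes_and_slab():
    vol = np.zeros((30, 60, 60), dtype=np.uint8)
    vol[5:25, 10:13, 10:13] = 1
    vol[5:25, 40:43, 40:43] = 1
    vol[27:30, :, :] = 1
    return LabelVolume(labels=vol, voxel_size=(1.0, 1.0, 1.0))


def test_isolate_glands_heuristic_lumen_and_bookkeeping():
    iso = isolate_glands(two_tubes_and_slab(), params=CastParams(min_component=50))
    assert iso.lumen_heuristic
    assert iso.lumen_voxels == 3 * 60 * 60
    assert len(iso.casts) == 2
    assert all(c.voxel_count == 20 * 9 for c in iso.casts)
    total = sum(c.voxel_count for c in iso.casts) + iso.lumen_voxels + iso.removed_voxels
    assert total == iso.total_foreground


def test_isolate_glands_with_seed_and_bad_seed():
    mask = two_tubes_and_slab()
    iso = isolate_glands(mask, lumen_seed=(28, 30, 30), params=CastParams(min_component=50))
    assert not iso.lumen_heuristic and iso.lumen_voxels == 10800
    with pytest.warns(UserWarning, match="background"):
        iso = isolate_glands(mask, lumen_seed=(0, 0, 0), params=CastParams(min_component=50))
    assert iso.lumen_heuristic


def test_isolate_glands_empty_mask():
    iso = isolate_glands(LabelVolume(np.zeros((4, 4, 4), np.uint8)))
    assert iso.casts == [] and iso.lumen_id is None and iso.total_foreground == 0


def test_cylinder_descriptors():
    # straight tube, radius 3 vox, length 50 vox, isotropic 1 um
    vol = np.zeros((12, 60, 12), dtype=np.uint8)
    zz, xx = np.ogrid[:12, :12]
    disk = (zz - 6) ** 2 + (xx - 6) ** 2 <= 3**2
    for y in range(5, 55):
        vol[:, y, :] |= disk.astype(np.uint8)
    vol[:, :2, :] = 1  # slab to act as the lumen
    iso = isolate_glands(LabelVolume(labels=vol, voxel_size=(1.0, 1.0, 1.0)),
                         lumen_seed=(0, 0, 0), params=CastParams(min_component=10))
    assert len(iso.casts) == 1
    c = iso.casts[0]
    assert c.principal_length == pytest.approx(50.0, abs=2.0)
    assert c.mean_width == pytest.approx(6.0, abs=1.0)
    assert c.volume == c.voxel_count * 1.0
    assert c.principal_length >= c.mean_width >= 0


def test_conservation_on_random_volumes(rng):
    from scipy import ndimage as ndi

    for _ in range(5):
        blob = ndi.gaussian_filter(rng.standard_normal((16, 32, 32)), 2.0)
        mask = LabelVolume((blob > 0.3).astype(np.uint8), voxel_size=(1, 1, 1))
        iso = isolate_glands(mask, params=CastParams(min_component=20))
        total = sum(c.voxel_count for c in iso.casts) + iso.lumen_voxels + iso.removed_voxels
        assert total == iso.total_foreground == int(mask.labels.sum())
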