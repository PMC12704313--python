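"""ROI intensities, compass thickness, ratio maps, fold change and stage stats."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import small_params
from shgcast.imgio import VolumeScan
from shgcast.intensity import (
    RoiBox,
    RoiDisk,
    auto_place_rois,
    averaged_roi_intensity,
    cage_fold_change_3d,
    cage_to_stroma_ratio,
    compare_stages,
    compass_thickness,
    ratio_map,
    roi_mean,
)
from shgcast.phantom import generate_phantom, stage_preset, truth_negative_space


def make_scan(arr, vs=(1.0, 1.0, 1.0)):
    return VolumeScan(np.asarray(arr, dtype=np.uint16), voxel_size=vs, bit_depth=16)


def test_roi_mean_constant_and_arithmetic():
    scan = make_scan(np.full((4, 8, 8), 7))
    assert roi_mean(scan, RoiBox((0, 0, 0), (4, 8, 8))).mean == 7.0
    scan = make_scan(np.array([[[1, 2], [3, 4]]]))
    s = roi_mean(scan, RoiBox((0, 0, 0), (1, 2, 2)))
    assert s.mean == 2.5 and s.min == 1 and s.max == 4 and s.count == 4


def test_roi_out_of_bounds_rejected():
    scan = make_scan(np.zeros((2, 4, 4)))
    with pytest.raises(ValueError, match="outside"):
        roi_mean(scan, RoiBox((0, 2, 2), (1, 4, 4)))
    with pytest.raises(ValueError, match="outside"):
        roi_mean(scan, RoiDisk(center=(2, 2), radius=3, z_range=(0, 1)))


def test_partition_additivity(rng):
    vox = rng.integers(0, 1000, (4, 6, 6))
    scan = make_scan(vox)
    whole = roi_mean(scan, RoiBox((0, 0, 0), (4, 6, 6)))
    parts = [RoiBox((0, 0, 0), (4, 3, 6)), RoiBox((0, 3, 0), (4, 2, 6)),
             RoiBox((0, 5, 0), (4, 1, 6))]
    stats = [roi_mean(scan, r) for r in parts]
    pooled = sum(s.mean * s.count for s in stats) / sum(s.count for s in stats)
    assert pooled == pytest.approx(whole.mean)


def test_averaged_roi_intensity_is_mean_of_means():
    vox = np.zeros((1, 3, 9))
    vox[0, :, 0:3] = 10
    vox[0, :, 3:6] = 20
    vox[0, :, 6:9] = 30
    scan = make_scan(vox)
    rois = [RoiBox((0, 0, 3 * i), (1, 3, 3)) for i in range(3)]
    avg, per = averaged_roi_intensity(scan, rois)
    assert avg == 20.0 and per == [10.0, 20.0, 30.0]
    one, _ = averaged_roi_intensity(scan, rois[:1])
    assert one == roi_mean(scan, rois[0]).mean
    with pytest.raises(ValueError):
        averaged_roi_intensity(scan, [])


def test_cage_to_stroma_ratio_arithmetic_and_self_ratio():
    vox = np.zeros((1, 2, 10))
    vox[0, 0] = 29  # "cage" strip
    vox[0, 1] = 10  # "stroma" strip
    scan = make_scan(vox)
    cage = [RoiBox((0, 0, i * 2), (1, 1, 2)) for i in range(5)]
    stroma = [RoiBox((0, 1, i * 2), (1, 1, 2)) for i in range(5)]
    assert cage_to_stroma_ratio(scan, cage, stroma) == pytest.approx(2.90)
    assert cage_to_stroma_ratio(scan, stroma, stroma) == 1.0


def test_ratio_map_normalizes_to_unit_mean(rng):
    img = rng.integers(1, 5000, (20, 30)).astype(float)
    out = ratio_map(img)
    assert out.mean() == pytest.approx(1.0, abs=1e-9)
    assert np.all(ratio_map(np.full((4, 4), 7.0)) == 1.0)
    np.testing.assert_allclose(ratio_map(np.array([1.0, 3.0])), [0.5, 1.5])
    with pytest.raises(ValueError):
        ratio_map(np.zeros((3, 3)))


def annulus(shape=(41, 41), center=(20, 20), r_in=6, r_out=10, value=100.0):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    img = np.zeros(shape)
    img[(r >= r_in) & (r < r_out)] = value
    return img


def test_compass_thickness_on_annulus():
    m = compass_thickness(annulus(), (20, 20), threshold=50.0, pixel_size=(1, 1))
    assert (m.t_north, m.t_south, m.t_east, m.t_west) == (4.0, 4.0, 4.0, 4.0)
    assert m.mean_thickness == 4.0
    assert m.flags == (False, False, False, False)


def test_compass_thickness_anisotropic_pixels():
    # ring of 3-pixel radial width, y spacing 2 um, x spacing 1 um
    m = compass_thickness(annulus(r_in=6, r_out=9), (20, 20),
                          threshold=50.0, pixel_size=(2.0, 1.0))
    assert m.t_north == 6.0 and m.t_south == 6.0
    assert m.t_east == 3.0 and m.t_west == 3.0


def test_compass_flags_when_no_cage_met():
    m = compass_thickness(np.zeros((11, 11)), (5, 5), threshold=10.0)
    assert m.mean_thickness == 0.0
    assert all(m.flags)
    with pytest.raises(ValueError, match="below-threshold"):
        compass_thickness(np.full((5, 5), 99.0), (2, 2), threshold=10.0)


def test_compass_recovers_random_annuli_within_one_pixel(rng):
    for _ in range(20):
        r_in = float(rng.integers(3, 15))
        width = float(rng.integers(2, 6))
        off = rng.uniform(-1, 1, size=2)
        center = (40 + off[0], 40 + off[1])
        img = annulus((81, 81), center, r_in, r_in + width)
        m = compass_thickness(img, (40, 40), threshold=50.0)
        for t in (m.t_north, m.t_south, m.t_east, m.t_west):
            assert abs(t - width) <= 1.0


def test_fold_change_self_normalized_roi_is_unity():
    scan = make_scan(np.full((6, 20, 20), 30))
    roi = RoiDisk(center=(10, 10), radius=8, z_range=(0, 6))
    assert cage_fold_change_3d(scan, (0, 6), roi) == pytest.approx(1.0)
    assert cage_fold_change_3d(scan, (0, 6), roi, normalizer="roi") == pytest.approx(1.0)


def test_fold_change_bright_cluster_above_unity():
    vox = np.full((4, 20, 20), 10.0)
    vox[:, 8:13, 8:13] = 100.0
    scan = make_scan(vox)
    roi = RoiDisk(center=(10, 10), radius=2, z_range=(0, 4))
    assert cage_fold_change_3d(scan, (0, 4), roi) > 1.0
    # roi-restricted normalizer is self-referential by construction
    assert cage_fold_change_3d(scan, (0, 4), roi, normalizer="roi") == pytest.approx(1.0)


def test_compare_stages_identical_groups_f_zero():
    res = compare_stages({k: [5.0, 5.0, 5.0] for k in "abcd"})
    assert res.anova_F == 0.0
    assert all(p == 1.0 for p in res.tukey.values())
    assert len(res.tukey) == 6


def test_compare_stages_separated_groups():
    res = compare_stages({"lo": [0.0, 0.1, -0.1], "hi": [10.0, 10.1, 9.9]})
    assert res.anova_p < 1e-6
    assert res.levene_p > 0.05
    assert all(v is not None and v > 0.05 for v in res.shapiro_p.values())


def test_compare_stages_matches_scipy_tukey_oracle(rng):
    groups = {k: list(rng.normal(loc, 1.0, size=6)) for k, loc in
              [("a", 0.0), ("b", 1.0), ("c", 3.0)]}
    res = compare_stages(groups)
    oracle = sps.tukey_hsd(*[np.asarray(v) for v in groups.values()])
    names = list(groups)
    for i in range(3):
        for j in range(i + 1, 3):
            key = tuple(sorted((names[i], names[j])))
            got = res.tukey[key]
            assert got == pytest.approx(oracle.pvalue[i, j], abs=1e-6)
    f_or, p_or = sps.f_oneway(*groups.values())
    assert res.anova_F == pytest.approx(f_or)
    assert res.anova_p == pytest.approx(p_or)


def test_compare_stages_input_validation():
    with pytest.raises(ValueError):
        compare_stages({"only": [1, 2, 3]})
    with pytest.raises(ValueError):
        compare_stages({"a": [1.0], "b": [1, 2]})
    res = compare_stages({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    assert res.shapiro_p["a"] is None  # too small for a normality test


def test_roi_recovery_on_phantom_stroma():
    # stroma-only phantom: five 50x50x50 um cubes recover the stromal mean
    params = small_params(shape=(56, 96, 96), n_glands=0, lumen_present=False,
                          myometrium_present=False, noise_sd=25.0)
    truth = generate_phantom(params)
    rois = auto_place_rois(truth.labels, 0, (50, 63, 63), 5, seed=7)
    avg, _ = averaged_roi_intensity(truth.scan, rois)
    assert avg == pytest.approx(params.stroma_mean, rel=0.05)


def test_cage_ratio_recovery_on_estrus_phantom():
    truth = generate_phantom(stage_preset("estrus", seed=3))
    lab = truth.labels
    neg = truth_negative_space(truth).labels.astype(bool)
    gen = np.random.default_rng(3)
    cage = auto_place_rois(lab, 2, (1, 3, 3), 5, seed=gen)
    stroma = auto_place_rois(lab, 0, (8, 12, 12), 5, seed=gen,
                             avoid=neg, avoid_margin_um=truth.params.cage_thickness + 1)
    r = cage_to_stroma_ratio(truth.scan, cage, stroma)
    assert 0.87 <= r <= 2.90 * 1.1
    assert r == pytest.approx(2.9, rel=0.10)


def test_auto_place_rois_stay_inside_class(small_truth):
    rois = auto_place_rois(small_truth.labels, 0, (4, 6, 6), 4, seed=0)
    lab = small_truth.labels.labels
    for r in rois:
        assert np.all(lab[r.slices()] == 0)
    with pytest.raises(ValueError):
        auto_place_rois(small_truth.labels, 9, (1, 1, 1), 1, seed=0)
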