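"""Texture-matrix statistics against exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

from repsurv import (
    FeatureConfig,
    extract_all_features,
    feature_names,
    glzsm_features,
    gtsdm_features,
    histogram_stats,
    ngtdm_features,
    quantize_region,
    shape_features,
    volumetric_features,
)
from repsurv.texture import UNIQUE_DIRECTIONS_3D, LabeledStudy, QuantizedRegion

from conftest import SMALL_SEMI_AXES
from repsurv import gen_phantom_study


# ----------------------------------------------------------------------
# brute-force oracles (naive voxel loops, independent of the implementation)
# ----------------------------------------------------------------------

def oracle_cooccurrence(levels, offset, n_levels):
    m = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for idx in itertools.product(*(range(s) for s in shape)):
        jdx = tuple(i + o for i, o in zip(idx, offset))
        if all(0 <= j < s for j, s in zip(jdx, shape)):
            a, b = levels[idx], levels[jdx]
            if a > 0 and b > 0:
                m[a - 1, b - 1] += 1
                m[b - 1, a - 1] += 1
    return m / m.sum() if m.sum() else None


def oracle_gtsdm_autocorrelation(levels, n_levels, directions=UNIQUE_DIRECTIONS_3D):
    vals = []
    for off in directions:
        p = oracle_cooccurrence(levels, off, n_levels)
        if p is None:
            continue
        i = np.arange(1, n_levels + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        vals.append((ii * jj * p).sum())
    return np.mean(vals)


def oracle_ngtdm(levels, n_levels):
    """Amadasun-King s_i, p_i by explicit neighborhood loops."""
    shape = levels.shape
    s = np.zeros(n_levels + 1)
    n = np.zeros(n_levels + 1)
    for idx in itertools.product(*(range(d) for d in shape)):
        if levels[idx] == 0:
            continue
        nbrs = []
        for off in itertools.product((-1, 0, 1), repeat=len(shape)):
            if all(o == 0 for o in off):
                continue
            jdx = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= j < d for j, d in zip(jdx, shape)) and levels[jdx] > 0:
                nbrs.append(levels[jdx])
        if not nbrs:
            continue
        lev = levels[idx]
        s[lev] += abs(lev - np.mean(nbrs))
        n[lev] += 1
    total = n.sum()
    p = n / total
    occ = np.flatnonzero(n[1:]) + 1
    strength_num = sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ)
    return {"strength": strength_num / (1e-12 + s.sum()), "s": s, "p": p, "n_vox": total}


def oracle_zones(levels, level):
    """Connected zones (26-connectivity) of one gray level by flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    sizes = []
    for start in itertools.product(*(range(d) for d in shape)):
        if levels[start] != level or seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            idx = stack.pop()
            size += 1
            for off in itertools.product((-1, 0, 1), repeat=len(shape)):
                jdx = tuple(i + o for i, o in zip(idx, off))
                if all(0 <= j < d for j, d in zip(jdx, shape)) \
                        and not seen[jdx] and levels[jdx] == level:
                    seen[jdx] = True
                    stack.append(jdx)
        sizes.append(size)
    return sizes


def oracle_glzsm(levels, n_levels):
    zones = {}
    for lev in range(1, n_levels + 1):
        for size in oracle_zones(levels, lev):
            zones[(lev, size)] = zones.get((lev, size), 0) + 1
    n_z = sum(zones.values())
    iv = np.array([k[0] for k in zones], float)
    jv = np.array([k[1] for k in zones], float)
    pz = np.array(list(zones.values()), float) / n_z
    return {
        "LGZE": (pz / iv ** 2).sum(),
        "LZE": (pz * jv ** 2).sum(),
        "LZLGE": (pz * jv ** 2 / iv ** 2).sum(),
        "SZE": (pz / jv ** 2).sum(),
    }


def _random_quantized(rng, n_levels=4):
    shape = tuple(rng.integers(3, 7, size=3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.85
    if mask.sum() < 4:
        mask[:2, :2, :2] = True
    levels = levels * mask
    return QuantizedRegion(levels=levels, mask=mask, n_levels=n_levels)


# ----------------------------------------------------------------------
# quantization
# ----------------------------------------------------------------------

class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        img = np.full((4, 4, 4), 7.0)
        q = quantize_region(img, np.ones_like(img, bool), 32)
        assert set(np.unique(q.levels)) == {1}

    def test_two_valued_region(self):
        img = np.zeros((2, 2, 2))
        img[0] = 10.0
        q = quantize_region(img, np.ones_like(img, bool), 2)
        assert set(np.unique(q.levels)) == {1, 2}

    def test_linear_ramp_one_voxel_per_level(self):
        img = np.arange(32, dtype=float).reshape(32, 1, 1)
        q = quantize_region(img, np.ones_like(img, bool), 32)
        counts = np.bincount(q.levels.ravel(), minlength=33)[1:]
        assert np.all(counts == 1)

    def test_empty_mask_refused(self):
        with pytest.raises(ValueError):
            quantize_region(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 8)

    def test_outside_mask_is_zero(self):
        img = np.random.default_rng(0).random((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        q = quantize_region(img, mask, 8)
        assert np.all(q.levels[~mask] == 0)
        assert np.all((q.levels[mask] >= 1) & (q.levels[mask] <= 8))


# ----------------------------------------------------------------------
# GTSDM
# ----------------------------------------------------------------------

class TestGtsdm:
    def test_constant_region(self):
        q = quantize_region(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool), 8)
        f = gtsdm_features(q)
        assert f["GTSDM_Autocorrelation"] == pytest.approx(1.0)
        assert f["GTSDM_Energy"] == pytest.approx(1.0)
        assert f["GTSDM_Contrast"] == pytest.approx(0.0)

    def test_checkerboard_single_offset(self):
        levels = np.array([[1, 2], [2, 1]], dtype=np.int32)[..., None]
        q = QuantizedRegion(levels=levels, mask=levels > 0, n_levels=2)
        f = gtsdm_features(q, distance=1, directions=[(0, 1, 0)])
        # the two ordered pairs per row are (1,2) and (2,1): p(1,2)=p(2,1)=0.5
        assert f["GTSDM_Autocorrelation"] == pytest.approx(2.0)
        assert f["GTSDM_Energy"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_autocorrelation_matches_bruteforce(self, seed):
        q = _random_quantized(np.random.default_rng(seed))
        f = gtsdm_features(q)
        expected = oracle_gtsdm_autocorrelation(q.levels, q.n_levels)
        assert f["GTSDM_Autocorrelation"] == pytest.approx(expected, rel=1e-10)

    def test_affine_intensity_invariance(self, rng):
        img = rng.random((5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        f1 = gtsdm_features(quantize_region(img, mask, 8))
        f2 = gtsdm_features(quantize_region(3.0 * img + 11.0, mask, 8))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)

    def test_per_direction_naming(self):
        q = quantize_region(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool), 4)
        f = gtsdm_features(q, per_direction=True)
        assert "GTSDM_d1_Autocorrelation" in f
        # all directions identical on a constant region
        assert f["GTSDM_d1_Autocorrelation"] == f["GTSDM_Autocorrelation"]


# ----------------------------------------------------------------------
# NGTDM
# ----------------------------------------------------------------------

class TestNgtdm:
    def test_constant_region_zero_strength(self):
        q = quantize_region(np.full((4, 4, 4), 2.0), np.ones((4, 4, 4), bool), 8)
        f = ngtdm_features(q)
        assert f["NGTDM_Strength"] == pytest.approx(0.0)
        assert f["NGTDM_Contrast"] == pytest.approx(0.0)

    def test_striped_block_matches_hand_enumeration(self):
        img = np.zeros((2, 3, 3))
        img[1] = 10.0
        q = quantize_region(img, np.ones_like(img, bool), 2)
        f = ngtdm_features(q)
        expected = oracle_ngtdm(q.levels, 2)
        assert f["NGTDM_Strength"] == pytest.approx(expected["strength"], rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_strength_matches_bruteforce(self, seed):
        q = _random_quantized(np.random.default_rng(100 + seed))
        f = ngtdm_features(q)
        expected = oracle_ngtdm(q.levels, q.n_levels)
        assert f["NGTDM_Strength"] == pytest.approx(expected["strength"], rel=1e-9)

    def test_shift_invariance(self, rng):
        img = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        f1 = ngtdm_features(quantize_region(img, mask, 6))
        f2 = ngtdm_features(quantize_region(img + 100.0, mask, 6))
        assert f1["NGTDM_Strength"] == pytest.approx(f2["NGTDM_Strength"], rel=1e-9)

    def test_single_voxel_refused(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        q = QuantizedRegion(levels=mask.astype(np.int32), mask=mask, n_levels=2)
        with pytest.raises(ValueError):
            ngtdm_features(q)


# ----------------------------------------------------------------------
# GLZSM
# ----------------------------------------------------------------------

class TestGlzsm:
    def test_constant_region_single_zone(self):
        n = 27
        q = quantize_region(np.full((3, 3, 3), 5.0), np.ones((3, 3, 3), bool), 8)
        f = glzsm_features(q)
        assert f["GLZSM_LargeZoneEmphasis"] == pytest.approx(n ** 2)
        assert f["GLZSM_Low_Gray_Level_Zone_Emphasis"] == pytest.approx(1.0)

    def test_toy_grid_matches_flood_fill(self):
        # one 12-voxel zone of level 1 and four singleton zones of level 2
        levels = np.ones((4, 4), dtype=np.int32)
        for i, j in ((0, 0), (0, 3), (3, 0), (3, 3)):
            levels[i, j] = 2
        levels = levels[..., None]
        q = QuantizedRegion(levels=levels, mask=levels > 0, n_levels=2)
        f = glzsm_features(q)
        expected = oracle_glzsm(levels, 2)
        assert f["GLZSM_LargeZoneEmphasis"] == pytest.approx(expected["LZE"])
        assert f["GLZSM_Low_Gray_Level_Zone_Emphasis"] == pytest.approx(expected["LGZE"])
        assert f["GLZSM_LargeZoneLowGrayEmphasis"] == pytest.approx(expected["LZLGE"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        q = _random_quantized(np.random.default_rng(200 + seed))
        f = glzsm_features(q)
        expected = oracle_glzsm(q.levels, q.n_levels)
        assert f["GLZSM_LargeZoneEmphasis"] == pytest.approx(expected["LZE"], rel=1e-10)
        assert f["GLZSM_Low_Gray_Level_Zone_Emphasis"] == pytest.approx(expected["LGZE"], rel=1e-10)
        assert f["GLZSM_LargeZoneLowGrayEmphasis"] == pytest.approx(expected["LZLGE"], rel=1e-10)
        assert f["GLZSM_SmallZoneEmphasis"] == pytest.approx(expected["SZE"], rel=1e-10)

    def test_splitting_a_zone_decreases_lze(self):
        solid = np.ones((1, 9, 1), dtype=np.int32)
        split = solid.copy()
        split[0, 4, 0] = 2
        f_solid = glzsm_features(QuantizedRegion(solid, solid > 0, 2))
        f_split = glzsm_features(QuantizedRegion(split, split > 0, 2))
        assert f_split["GLZSM_LargeZoneEmphasis"] < f_solid["GLZSM_LargeZoneEmphasis"]


# ----------------------------------------------------------------------
# histogram / shape / volume
# ----------------------------------------------------------------------

class TestHistogram:
    def test_constant_region(self):
        f = histogram_stats(np.full((4, 4, 4), 3.5), np.ones((4, 4, 4), bool))
        assert f["Histogram_Mean"] == pytest.approx(3.5)
        assert f["Histogram_Variance"] == 0.0
        assert f["Histogram_Entropy"] == 0.0
        assert f["Histogram_Energy"] == 1.0
        assert f["Histogram_Skewness"] == 0.0

    def test_symmetric_two_point(self):
        img = np.array([-2.0, 2.0] * 8).reshape(4, 2, 2)
        f = histogram_stats(img, np.ones_like(img, bool))
        assert f["Histogram_Mean"] == pytest.approx(0.0)
        assert f["Histogram_Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_moments(self, rng):
        img = rng.standard_normal(100_000)
        f = histogram_stats(img, np.ones_like(img, bool))
        assert abs(f["Histogram_Mean"]) < 0.02
        assert abs(f["Histogram_Variance"] - 1.0) < 0.03


class TestShape:
    def test_sphere(self):
        g = np.mgrid[:24, :24, :24]
        mask = sum((x - 11.5) ** 2 for x in g) <= 10.0 ** 2
        f = shape_features(mask)
        assert f["Eccentricity"] <= 0.05
        lens = [f["FirstAxisLength"], f["SecondAxisLength"], f["ThirdAxisLength"]]
        assert max(lens) / min(lens) <= 1.05

    def test_axis_aligned_ellipsoid_ratios(self):
        g = np.mgrid[:48, :28, :16].astype(float)
        c = (23.5, 13.5, 7.5)
        mask = ((g[0] - c[0]) / 20) ** 2 + ((g[1] - c[1]) / 10) ** 2 \
            + ((g[2] - c[2]) / 5) ** 2 <= 1.0
        f = shape_features(mask)
        # continuous uniform ellipsoid: eigenvalues a^2/5 -> lengths ratio 4:2:1
        assert f["FirstAxisLength"] / f["SecondAxisLength"] == pytest.approx(2.0, rel=0.05)
        assert f["SecondAxisLength"] / f["ThirdAxisLength"] == pytest.approx(2.0, rel=0.07)
        for k in ("Orientation_1", "Orientation_2", "Orientation_3"):
            assert f[k] == pytest.approx(0.0, abs=3.0)

    def test_full_cuboid_extent_one(self):
        f = shape_features(np.ones((6, 5, 4), bool))
        assert f["Extent"] == pytest.approx(1.0)

    def test_translation_invariance_and_spacing_scaling(self):
        base = np.zeros((20, 20, 20), bool)
        base[3:9, 4:12, 5:9] = True
        shifted = np.roll(base, (4, 3, 5), axis=(0, 1, 2))
        f1 = shape_features(base)
        f2 = shape_features(shifted)
        for k in ("FirstAxisLength", "SecondAxisLength", "ThirdAxisLength",
                  "Eccentricity", "Extent"):
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)
        f3 = shape_features(base, spacing=(2.0, 2.0, 2.0))
        assert f3["FirstAxisLength"] == pytest.approx(2.0 * f1["FirstAxisLength"])


class TestVolumetric:
    def test_thousand_voxels(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[:10, :10, :10] = 2
        f = volumetric_features(labels, np.ones_like(labels, bool))
        assert f["wt_Volume"] == 1000.0
        assert f["edema_Volume"] == 1000.0

    def test_tumor_equals_brain_gives_ratio_one(self):
        labels = np.full((5, 5, 5), 2, dtype=np.int16)
        f = volumetric_features(labels, np.ones_like(labels, bool))
        assert f["wt_brain_VolumeRatio"] == 1.0

    def test_partition_additivity_on_phantom(self, phantom):
        f = volumetric_features(phantom.labels, phantom.brain_mask(), phantom.spacing)
        assert f["wt_Volume"] == pytest.approx(
            f["nec_Volume"] + f["edema_Volume"] + f["et_Volume"])

    def test_tumor_outside_brain_refused(self, phantom):
        with pytest.raises(ValueError, match="outside"):
            volumetric_features(phantom.labels, ~phantom.brain_mask(), phantom.spacing)

    def test_bad_label_code_refused(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 3
        with pytest.raises(ValueError, match="label codes"):
            volumetric_features(labels, np.ones_like(labels, bool))


# ----------------------------------------------------------------------
# full extraction
# ----------------------------------------------------------------------

class TestExtractAll:
    def test_row_matches_config_enumeration(self, phantom_study, small_feature_config):
        row = extract_all_features(phantom_study, small_feature_config)
        assert len(row) == small_feature_config.n_features
        assert list(row.index) == feature_names(small_feature_config)

    def test_deterministic(self, phantom_study, small_feature_config):
        a = extract_all_features(phantom_study, small_feature_config)
        b = extract_all_features(phantom_study, small_feature_config)
        assert a.equals(b)

    def test_published_feature_names_present(self, small_feature_config):
        names = feature_names(small_feature_config)
        for required in (
            "ET2", "L1_Extent", "L2_Orientation", "L3_Orientation",
            "wt_MajorAxisLength", "edema_FirstAxisLength", "nec_SecondAxis_1",
            "T1C_ED_Histogram_Mean", "T1C_ED_Histogram_Skewness", "ED_up_left_y",
            "T1C_mBm_GLZSM_LargeZoneLowGrayEmphasis",
            "T1C_ptpsa_GLZSM_Low_Gray_Level_Zone_Emphasis",
            "T1C_GTSDM_Autocorrelation", "T1C_NGTDM_Strength",
        ):
            assert required in names

    def test_enlarged_necrosis_has_longer_second_axis(self):
        small = gen_phantom_study(semi_axes=SMALL_SEMI_AXES, noise_sd=0.5,
                                  seed=2, size=40)
        big_axes = dict(SMALL_SEMI_AXES, necrosis=(8.0, 7.0, 5.5))
        big = gen_phantom_study(semi_axes=big_axes, noise_sd=0.5, seed=2, size=40)
        cfg = FeatureConfig(sources=("",))
        r_small = extract_all_features(
            LabeledStudy(small.intensity, small.labels, small.spacing, "a",
                         small.brain_mask()), cfg)
        r_big = extract_all_features(
            LabeledStudy(big.intensity, big.labels, big.spacing, "b",
                         big.brain_mask()), cfg)
        assert r_big["nec_SecondAxis_1"] > r_small["nec_SecondAxis_1"]

    def test_missing_region_yields_nan_row_still_produced(self):
        labels = np.zeros((24, 24, 24), dtype=np.int16)
        labels[8:16, 8:16, 8:16] = 2  # edema only
        study = LabeledStudy(np.random.default_rng(0).random((24, 24, 24)) * 50,
                             labels, (1.0, 1.0, 1.0), "partial")
        cfg = FeatureConfig(sources=("",), ptpsa_window=4, ptpsa_scales=(1, 2, 4))
        row = extract_all_features(study, cfg)
        assert len(row) == cfg.n_features
        assert np.isnan(row["T1C_NEC_GTSDM_Autocorrelation"])
        assert np.isfinite(row["T1C_ED_GTSDM_Autocorrelation"])
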