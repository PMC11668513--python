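import numpy as np
import pytest

from rdpa import (
    VolumePair,
    coloc_coefficients,
    count_foci,
    region_mean_intensity,
    rotation_null,
    segment_nuclei,
)
from rdpa.simulate import ImageConfig, generate_image_stack


def ellipsoid_mask(shape, center, semi):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], -1).astype(float)
    return (((coords - np.asarray(center)) / np.asarray(semi)) ** 2).sum(-1) <= 1


class TestSegmentNuclei:
    def test_single_ellipsoid_recovered(self):
        nuc = generate_image_stack(seed=0)
        labels = segment_nuclei(nuc.dapi, sigma=2.0)
        assert labels.max() == 1
        seg = labels == 1
        jaccard = (seg & nuc.mask).sum() / (seg | nuc.mask).sum()
        assert jaccard >= 0.9

    def test_two_separated_ellipsoids(self):
        rng = np.random.default_rng(1)
        shape = (30, 90, 40)
        vol = np.zeros(shape)
        m1 = ellipsoid_mask(shape, (15, 22, 20), (9, 13, 11))
        m2 = ellipsoid_mask(shape, (15, 66, 20), (9, 13, 11))
        vol[m1] = 5.0
        vol[m2] = 5.0
        vol += rng.normal(0, 0.5, shape)
        labels = segment_nuclei(np.clip(vol, 0, None), sigma=2.0)
        assert labels.max() == 2

    def test_blank_volume(self):
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_nuclei(np.zeros((10, 10, 10)))
        assert labels.max() == 0


class TestCountFoci:
    def test_planted_foci_recovered(self):
        nuc = generate_image_stack(ImageConfig(n_foci=3), seed=2)
        count, _ = count_foci(nuc.target, nuc.mask)
        assert count == 3

    def test_eight_voxel_object_excluded(self):
        # 2x2x2 bright cube: 8 voxels < the 10-voxel minimum size filter
        shape = (20, 20, 20)
        mask = np.ones(shape, bool)
        vol = np.ones(shape)
        vol[9:11, 9:11, 9:11] = 50.0
        count, _ = count_foci(vol, mask, sigma=0.0, min_voxels=10)
        assert count == 0
        count, _ = count_foci(vol, mask, sigma=0.0, min_voxels=8)
        assert count == 1

    def test_focus_outside_mask_not_counted(self):
        shape = (24, 40, 40)
        mask = ellipsoid_mask(shape, (12, 12, 12), (8, 8, 8))
        vol = np.ones(shape) * 0.5
        vol[12, 30, 30] = 100.0  # bright point well outside the mask
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        blob = 10 * np.exp(-(((zz - 12) ** 2 + (yy - 30) ** 2 + (xx - 30) ** 2) / 8))
        count, _ = count_foci(vol + blob, mask, sigma=1.0)
        assert count == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            count_foci(np.ones((5, 5, 5)), np.zeros((5, 5, 5), bool))

    def test_count_invariant_under_intensity_scaling(self):
        nuc = generate_image_stack(ImageConfig(n_foci=6), seed=3)
        c1, _ = count_foci(nuc.target, nuc.mask)
        c2, _ = count_foci(nuc.target * 7.3, nuc.mask)
        assert c1 == c2 == 6

    def test_count_invariant_under_joint_rotation(self):
        nuc = generate_image_stack(ImageConfig(n_foci=4), seed=4)
        c1, _ = count_foci(nuc.target, nuc.mask)
        rot = np.rot90(nuc.target, k=1, axes=(1, 2))
        rot_mask = np.rot90(nuc.mask, k=1, axes=(1, 2))
        c2, _ = count_foci(rot, rot_mask)
        assert c1 == c2


class TestColocCoefficients:
    def test_identical_channels(self, rng):
        v = rng.uniform(0, 10, (12, 20, 20))
        res = coloc_coefficients(VolumePair(v, v.copy()))
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)
        assert res.manders_m1 == pytest.approx(1.0)
        assert res.manders_m2 == pytest.approx(1.0)

    def test_anticorrelated_channels(self, rng):
        v = rng.uniform(0, 10, (12, 20, 20))
        res = coloc_coefficients(VolumePair(v, v.max() - v))
        assert res.pearson == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        v1 = rng.uniform(0, 1, (50, 50, 50))
        v2 = rng.uniform(0, 1, (50, 50, 50))
        res = coloc_coefficients(VolumePair(v1, v2))
        assert abs(res.pearson) < 0.02

    def test_constant_channel_gives_nan(self, rng):
        v = rng.uniform(0, 1, (10, 10, 10))
        with pytest.warns(UserWarning, match="constant"):
            res = coloc_coefficients(VolumePair(v, np.ones_like(v)))
        assert np.isnan(res.pearson)

    def test_manders_bounds_random_inputs(self, rng):
        for _ in range(10):
            v1 = rng.gamma(2, 1, (8, 15, 15))
            v2 = rng.gamma(2, 1, (8, 15, 15))
            res = coloc_coefficients(VolumePair(v1, v2))
            assert 0.0 <= res.manders_m1 <= 1.0
            assert 0.0 <= res.manders_m2 <= 1.0

    def test_pearson_matches_textbook_covariance(self, rng):
        v1 = rng.uniform(0, 5, (10, 12, 12))
        v2 = v1 * 0.5 + rng.uniform(0, 1, (10, 12, 12))
        res = coloc_coefficients(VolumePair(v1, v2))
        a, b = v1.ravel(), v2.ravel()
        cov = ((a - a.mean()) * (b - b.mean())).sum() / (a.size - 1)
        r = cov / (a.std(ddof=1) * b.std(ddof=1))
        assert res.pearson == pytest.approx(r, abs=1e-12)


class TestRotationNull:
    def _symmetric_pair(self):
        shape = (10, 41, 41)
        mask = ellipsoid_mask(shape, (5, 20, 20), (5, 18, 18))
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        r2 = (yy - 20.0) ** 2 + (xx - 20.0) ** 2
        blob = 5 * np.exp(-r2 / 60) + 0.1
        ch1 = blob * 0.8 + 0.2
        return VolumePair(ch1, blob, mask)

    def test_rotationally_symmetric_channel_unchanged(self):
        pair = self._symmetric_pair()
        base = coloc_coefficients(pair)
        for angle in (90, 180, 270):
            rot = rotation_null(pair, angle)
            assert rot.pearson == pytest.approx(base.pearson, abs=1e-6)

    def test_colocated_foci_decorrelate_under_rotation(self):
        nuc = generate_image_stack(
            ImageConfig(n_foci=8, coloc_fraction=1.0, noise_sd=0.1), seed=5
        )
        pair = VolumePair(nuc.target, nuc.second, nuc.mask)
        real = coloc_coefficients(pair)
        null = rotation_null(pair, 90)
        assert real.pearson > 0.8
        assert null.pearson < real.pearson - 0.5

    def test_deterministic(self):
        nuc = generate_image_stack(ImageConfig(n_foci=5, coloc_fraction=0.5), seed=6)
        pair = VolumePair(nuc.target, nuc.second, nuc.mask)
        a = rotation_null(pair, 180)
        b = rotation_null(pair, 180)
        assert a == b

    def test_bad_angle_rejected(self):
        pair = self._symmetric_pair()
        with pytest.raises(ValueError):
            rotation_null(pair, 45)


class TestRegionMeanIntensity:
    def test_uniform_intensity(self):
        vol = np.full((6, 10, 10), 10.0)
        masks = {"Sp": np.zeros_like(vol, bool), "Np": np.zeros_like(vol, bool)}
        masks["Sp"][2, :5, :5] = True
        masks["Np"][3, 5:, 5:] = True
        out = region_mean_intensity(vol, masks, reference=10.0)
        assert out["Sp"] == pytest.approx(1.0)
        assert out["Np"] == pytest.approx(1.0)

    def test_half_intensity_region(self):
        vol = np.full((4, 8, 8), 5.0)
        mask = np.zeros_like(vol, bool)
        mask[1] = True
        out = region_mean_intensity(vol, {"R": mask}, reference=10.0)
        assert out["R"] == pytest.approx(0.5)

    def test_empty_region_is_nan(self):
        vol = np.ones((4, 8, 8))
        with pytest.warns(UserWarning, match="empty"):
            out = region_mean_intensity(vol, {"R": np.zeros_like(vol, bool)}, 1.0)
        assert np.isnan(out["R"])

    def test_speckle_vs_nucleoplasm_ratio(self, rng):
        from scipy import ndimage
        shape = (12, 30, 30)
        speckle = np.zeros(shape, bool)
        speckle[3:9, 8:20, 8:20] = True
        nucleoplasm = ~speckle
        vol = np.where(speckle, 3.0, 1.0) + rng.normal(0, 0.05, shape)
        blurred = ndimage.gaussian_filter(vol, 0.6)
        out = region_mean_intensity(blurred, {"Sp": speckle, "Np": nucleoplasm}, 1.0)
        assert out["Sp"] / out["Np"] == pytest.approx(3.0, abs=0.5)
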