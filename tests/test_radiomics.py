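import numpy as np
import pytest
from _oracles import brute_first_order, brute_glcm_imc1, brute_glrlm_features

from immunorad.radiomics import (DIRECTIONS_13, ExtractionConfig, ImageVolume,
                                 class_proportions, extract_all, first_order,
                                 glcm_imc1, glrlm_features,
                                 normalize_intensity, quantize, resample,
                                 shape_features, wavelet_bands)


class TestResample:
    def test_inplane_doubling(self, rng):
        vol = ImageVolume(rng.normal(size=(10, 10, 6)), (1.5, 1.5, 3.0))
        out = resample(vol, (0.75, 0.75, 3.0))
        assert out.voxels.shape == (20, 20, 6)
        assert out.spacing_mm == (0.75, 0.75, 3.0)

    def test_constant_stays_constant(self):
        vol = ImageVolume(np.full((8, 8, 8), 4.2), (1.0, 1.0, 1.0))
        out = resample(vol, (0.5, 0.5, 0.5))
        np.testing.assert_allclose(out.voxels, 4.2)

    def test_identity_when_spacing_matches(self, rng):
        vol = ImageVolume(rng.normal(size=(6, 6, 6)), (0.75, 0.75, 3.0))
        out = resample(vol, (0.75, 0.75, 3.0))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_mask_resampling_stays_binary(self, rng):
        mask = (rng.uniform(size=(10, 10, 6)) > 0.5).astype(float)
        vol = ImageVolume(mask, (1.5, 1.5, 3.0))
        out = resample(vol, (0.75, 0.75, 3.0), is_mask=True)
        assert set(np.unique(out.voxels)) <= {0.0, 1.0}

    def test_nonpositive_spacing_rejected(self, rng):
        vol = ImageVolume(rng.normal(size=(6, 6, 6)), (1, 1, 1))
        with pytest.raises(ValueError):
            resample(vol, (0.75, 0, 3.0))


class TestNormalizeIntensity:
    def test_mask_mean_maps_to_half(self, rng):
        vol = ImageVolume(rng.normal(3, 2, size=(8, 8, 8)), (1, 1, 1))
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        out = normalize_intensity(vol, mask)
        assert out.voxels[mask].mean() == pytest.approx(0.5, abs=1e-6)

    def test_affine_intensity_invariance(self, rng):
        base = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        a = normalize_intensity(ImageVolume(base, (1, 1, 1)), mask)
        b = normalize_intensity(ImageVolume(3.5 * base + 11.0, (1, 1, 1)), mask)
        np.testing.assert_allclose(a.voxels, b.voxels, atol=1e-12)

    def test_outliers_clip_to_unit_interval(self):
        vox = np.zeros((8, 8, 8))
        vox[0, 0, 0] = 100.0
        vox[0, 0, 1] = -100.0
        out = normalize_intensity(ImageVolume(vox, (1, 1, 1)),
                                  np.ones((8, 8, 8), bool))
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0

    def test_idempotent_without_clipping(self, rng):
        # bounded values: nothing reaches the +/-3 SD clip
        vox = rng.uniform(0, 1, size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        once = normalize_intensity(ImageVolume(vox, (1, 1, 1)), mask)
        twice = normalize_intensity(once, mask)
        np.testing.assert_allclose(twice.voxels, once.voxels, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_intensity(ImageVolume(np.ones((8, 8, 8)), (1, 1, 1)),
                                np.ones((8, 8, 8), bool))


class TestWaveletBands:
    def test_constant_volume_zero_details(self):
        bands = wavelet_bands(np.full((8, 8, 8), 3.0))
        for label, band in bands.items():
            if label != "LLL":
                np.testing.assert_allclose(band, 0.0, atol=1e-12)

    def test_haar_2x2x2_hand_computation(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        bands = wavelet_bands(vol, "haar")
        s = np.sqrt(2.0)

        def haar_axis(a, axis):
            lo = (a.take(0, axis) + a.take(1, axis)) / s
            hi = (a.take(0, axis) - a.take(1, axis)) / s
            return lo, hi

        expect = {}
        for lx, x in zip("LH", haar_axis(vol, 0)):
            for ly, y in zip("LH", haar_axis(np.expand_dims(x, 0), 1)):
                for lz, z in zip("LH", haar_axis(np.expand_dims(y, 0), 2)):
                    expect[lx + ly + lz] = z
        for label in expect:
            np.testing.assert_allclose(bands[label].ravel(),
                                       np.ravel(expect[label]), atol=1e-12)

    def test_parseval_energy_conservation(self, rng):
        vol = rng.normal(size=(8, 10, 6))
        bands = wavelet_bands(vol, "haar")
        total = sum(np.sum(b**2) for b in bands.values())
        assert total == pytest.approx(np.sum(vol**2), rel=1e-10)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            wavelet_bands(rng.normal(size=(1, 8, 8)))


class TestFirstOrder:
    def test_uniform_histogram_entropy_and_uniformity(self):
        out = first_order(np.array([1.0, 2.0, 3.0, 4.0]), n_bins=4)
        assert out["Entropy"] == pytest.approx(2.0)
        assert out["Uniformity"] == pytest.approx(0.25)

    def test_constant_roi_conventions(self):
        out = first_order(np.full(10, 7.0), n_bins=4)
        assert out["Variance"] == 0.0
        assert out["Range"] == 0.0
        assert out["Skewness"] == 0.0

    def test_direct_arithmetic(self):
        out = first_order(np.array([1.0, 2.0, 3.0, 4.0]), n_bins=4)
        assert out["Mean"] == pytest.approx(2.5)
        assert out["Root mean square"] == pytest.approx(np.sqrt(7.5))
        assert out["Third quartile"] == pytest.approx(3.25)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=50)
        a = first_order(x)
        b = first_order(rng.permutation(x))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            first_order(np.array([1.0]))


class TestGlrlm:
    def test_hand_enumerated_slab(self):
        # runs along +x (rows): (1,len2),(2,len1),(2,len3)
        levels = np.array([[1, 1, 2], [2, 2, 2]])[:, :, None]
        mask = np.ones_like(levels, bool)
        out = glrlm_features(levels, mask, directions=[(0, 1, 0)])
        assert out["SRE"] == pytest.approx((1 / 4 + 1 + 1 / 9) / 3)

    def test_checkerboard_sre_is_one(self):
        ix = np.indices((4, 4, 4)).sum(axis=0)
        levels = (ix % 2) + 1
        mask = np.ones_like(levels, bool)
        out = glrlm_features(levels, mask, directions=DIRECTIONS_13[:3])
        assert out["SRE"] == pytest.approx(1.0)

    def test_constant_extremes_among_two_level_blocks(self):
        """One long run minimizes SRE and maximizes LRHGLE over all
        2-level 2x2x2 volumes (brute-force enumeration)."""
        mask = np.ones((2, 2, 2), bool)
        direction = [(1, 0, 0)]
        sres, lrs = [], []
        for bits in range(256):
            levels = np.array([(bits >> i & 1) + 1 for i in range(8)],
                              dtype=np.int32).reshape(2, 2, 2)
            out = glrlm_features(levels, mask, directions=direction)
            sres.append(out["SRE"])
            lrs.append(out["LRHGLE"])
        const = glrlm_features(np.full((2, 2, 2), 2, np.int32), mask,
                               directions=direction)
        assert const["SRE"] == pytest.approx(min(sres))
        assert const["LRHGLE"] == pytest.approx(max(lrs))

    def test_matches_brute_force_all_two_level_volumes(self):
        """Exhaustive equivalence on every 2-level volume up to 3x3x1."""
        for nx in (1, 2, 3):
            for ny in (1, 2, 3):
                size = nx * ny
                for bits in range(2 ** size):
                    levels = np.array(
                        [(bits >> i & 1) + 1 for i in range(size)],
                        dtype=np.int32).reshape(nx, ny, 1)
                    mask = np.ones_like(levels, bool)
                    mine = glrlm_features(levels, mask, DIRECTIONS_13)
                    ref = brute_glrlm_features(levels, mask, DIRECTIONS_13)
                    for k in mine:
                        assert mine[k] == pytest.approx(ref[k], rel=1e-12), \
                            (nx, ny, bits, k)

    def test_masked_voxels_break_runs(self):
        levels = np.full((1, 5, 1), 1, np.int32)
        mask = np.ones((1, 5, 1), bool)
        mask[0, 2, 0] = False
        levels[~mask] = 0
        out = glrlm_features(levels, mask, directions=[(0, 1, 0)])
        # two runs of length 2: SRE = (1/4 + 1/4)/2
        assert out["SRE"] == pytest.approx(0.25)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((2, 2, 2), np.int32),
                           np.zeros((2, 2, 2), bool))


class TestGlcm:
    def test_independent_joint_distribution_zero(self, rng):
        # i.i.d. levels: empirical IMC1 ~ 0 for a large volume
        levels = rng.integers(1, 3, size=(40, 40, 1)).astype(np.int32)
        mask = np.ones_like(levels, bool)
        out = glcm_imc1(levels, mask, directions=[(1, 0, 0)])
        assert abs(out) < 0.01

    def test_dependent_stripes_minus_one(self):
        levels = np.array([[1, 1, 1, 1], [2, 2, 2, 2]] * 2,
                          dtype=np.int32)[:, :, None]
        mask = np.ones_like(levels, bool)
        out = glcm_imc1(levels, mask, directions=[(0, 1, 0)])
        assert out == pytest.approx(-1.0)

    def test_constant_roi_degenerate_zero(self):
        levels = np.full((3, 3, 1), 1, np.int32)
        with pytest.warns(UserWarning):
            out = glcm_imc1(levels, np.ones_like(levels, bool),
                            directions=[(0, 1, 0)])
        assert out == 0.0

    def test_matches_brute_force_all_two_level_volumes(self):
        for nx, ny in [(2, 2), (3, 2), (3, 3)]:
            size = nx * ny
            for bits in range(2 ** size):
                levels = np.array([(bits >> i & 1) + 1 for i in range(size)],
                                  dtype=np.int32).reshape(nx, ny, 1)
                mask = np.ones_like(levels, bool)
                mine = glcm_imc1(levels, mask, DIRECTIONS_13)
                ref = brute_glcm_imc1(levels, mask, DIRECTIONS_13)
                assert mine == pytest.approx(ref, abs=1e-12), (nx, ny, bits)


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        out = shape_features(mask, (1, 1, 1))
        assert out["Volume"] == pytest.approx(1.0)
        assert out["Surface area"] == pytest.approx(6.0)

    def test_cube_sphericity_closed_form(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        out = shape_features(mask, (1, 1, 1))
        assert out["Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3),
                                                  rel=1e-12)

    def test_sphericity_at_most_one(self, rng):
        for _ in range(5):
            mask = rng.uniform(size=(6, 6, 6)) > 0.4
            if not mask.any():
                continue
            out = shape_features(mask, (0.75, 0.75, 3.0))
            assert out["Sphericity"] <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((2, 2, 2), bool), (1, 1, 1))


class TestExtractAll:
    @pytest.fixture(scope="class")
    def volume_and_mask(self):
        rng = np.random.default_rng(3)
        vox = rng.normal(size=(12, 12, 8))
        mask = np.zeros((12, 12, 8), bool)
        mask[2:10, 2:10, 1:7] = True
        return ImageVolume(vox, (0.75, 0.75, 3.0)), mask

    def test_bands_disabled_names_carry_none(self, volume_and_mask):
        vol, mask = volume_and_mask
        fv = extract_all(vol, mask, ExtractionConfig(bands_enabled=False))
        assert all(name.startswith("none_") for name in fv.features)

    def test_deterministic(self, volume_and_mask):
        vol, mask = volume_and_mask
        a = extract_all(vol, mask)
        b = extract_all(vol, mask)
        assert a.features == b.features

    def test_class_proportions_sum_to_100(self, volume_and_mask):
        vol, mask = volume_and_mask
        fv = extract_all(vol, mask)
        props = class_proportions(fv.features)
        assert sum(props.values()) == pytest.approx(100.0)
        assert set(props) == {"first_order", "glrlm", "glcm", "shape"}

    def test_pre_transform_hook_adds_named_features(self, volume_and_mask):
        vol, mask = volume_and_mask
        cfg = ExtractionConfig(bands_enabled=False,
                               pre_transforms={"none": None,
                                               "SIFT": lambda v: v**2})
        fv = extract_all(vol, mask, cfg)
        assert any(n.startswith("none_SIFT_") for n in fv.features)
        assert any(n.startswith("none_none_") for n in fv.features)

    def test_shape_mismatch_rejected(self, volume_and_mask):
        vol, _ = volume_and_mask
        with pytest.raises(ValueError, match="shape"):
            extract_all(vol, np.ones((4, 4, 4), bool))

    def test_first_order_matches_oracle_inside_extract(self, volume_and_mask):
        vol, mask = volume_and_mask
        fv = extract_all(vol, mask, ExtractionConfig(bands_enabled=False))
        ref = brute_first_order(vol.voxels[mask], 32)
        for name, expected in ref.items():
            assert fv[f"none_none_{name}"] == pytest.approx(expected,
                                                            rel=1e-9)


def test_quantize_levels_within_range(rng):
    vox = rng.normal(size=(6, 6, 6))
    mask = rng.uniform(size=(6, 6, 6)) > 0.3
    lv = quantize(vox, mask, n_bins=8)
    assert lv[~mask].max() == 0
    assert 1 <= lv[mask].min() and lv[mask].max() <= 8
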