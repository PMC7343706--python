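import numpy as np
import pytest

from octplaq import (FEATURE_NAMES, attenuation_map, build_feature_stack,
                     fd_features, fd_slope, feature_subset, fos_features,
                     generate_phantom, glcm_features, ngtdm_features,
                     quantize)
from octplaq.io_oct import CALCIFIED, FIBROUS
from octplaq.phantom import PhantomSpec, TissueOpticalParams

from . import oracles


class TestFos:
    def test_constant_window_convention(self):
        assert fos_features(np.full((3, 3), 5.0)) == (5.0, 0.0, 5.0, 0.0,
                                                      0.0)

    def test_small_analytic_case(self):
        mean, var, med, skew, kurt = fos_features(np.array([1, 2, 3, 4.0]))
        assert (mean, var, med, skew) == (2.5, 1.25, 2.5, 0.0)

    def test_three_zeros_one_nine_skewness(self):
        """Direct-moment oracle value for {0,0,0,9}: skewness 2/sqrt(3)."""
        feats = fos_features(np.array([0.0, 0.0, 0.0, 9.0]))
        assert feats[3] == pytest.approx(2 / np.sqrt(3), abs=1e-12)
        oracle = oracles.moments_direct([0.0, 0.0, 0.0, 9.0])
        np.testing.assert_allclose(feats, oracle, atol=1e-12)

    def test_matches_streaming_oracle(self, rng):
        for _ in range(20):
            w = rng.uniform(-5, 17, size=(7, 7))
            mean, var = oracles.fos_streaming(w)
            feats = fos_features(w)
            assert feats[0] == pytest.approx(mean, abs=1e-12)
            assert feats[1] == pytest.approx(var, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fos_features(np.empty(0))


class TestGlcm:
    def test_constant_window(self):
        f = glcm_features(np.zeros((4, 4), dtype=int), levels=8)
        corr, contrast, dissim, energy, entropy, homog, maxp = f
        assert (energy, entropy, contrast, dissim) == (1.0, 0.0, 0.0, 0.0)
        assert (homog, maxp) == (1.0, 1.0)

    def test_two_row_patch_single_angle(self):
        """[[0,0],[1,1]] at 0 deg: P is diag(0.5, 0.5), so energy 0.5,
        entropy 1 bit, contrast 0 (verified by pair enumeration)."""
        qw = np.array([[0, 0], [1, 1]])
        P = oracles.glcm_matrix_bruteforce(qw, 2, 0)
        assert P == [[0.5, 0.0], [0.0, 0.5]]

    def test_checkerboard_row_single_angle(self):
        qw = np.array([[0, 1, 0, 1, 0, 1]])
        P = oracles.glcm_matrix_bruteforce(qw, 2, 0)
        # all pairs are (0,1) or (1,0): contrast 1, dissim 1, homog 0.5
        contrast = sum(P[i][j] * (i - j) ** 2 for i in range(2)
                       for j in range(2))
        dissim = sum(P[i][j] * abs(i - j) for i in range(2)
                     for j in range(2))
        homog = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(2)
                    for j in range(2))
        assert (contrast, dissim, homog) == (1.0, 1.0, 0.5)

    def test_matches_bruteforce_on_random_patches(self, rng):
        """Implementation equals explicit pair enumeration on random
        patches (up to double-precision round-off)."""
        for _ in range(30):
            qw = rng.integers(0, 6, size=(8, 8))
            got = glcm_features(qw, levels=6)
            want = oracles.glcm_features_bruteforce(qw, 6)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((1, 5), dtype=int), levels=4)

    def test_agrees_with_scikit_image(self, rng):
        """Independent library route: per-angle features match
        skimage.feature.graycoprops on random patches."""
        from skimage.feature import graycomatrix, graycoprops

        for _ in range(10):
            qw = rng.integers(0, 8, size=(9, 9)).astype(np.uint8)
            got = glcm_features(qw, levels=8)
            angles = [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
            G = graycomatrix(qw, [1], angles, levels=8, symmetric=True,
                             normed=True)
            for mine, prop in ((0, "correlation"), (1, "contrast"),
                               (2, "dissimilarity"), (5, "homogeneity")):
                want = graycoprops(G, prop)[0].mean()
                assert got[mine] == pytest.approx(want, rel=1e-10)
            assert got[3] == pytest.approx(graycoprops(G, "ASM")[0].mean(),
                                           rel=1e-10)


class TestNgtdm:
    def test_constant_window_guard(self):
        busy, contrast, cmplx, coarse, strength = ngtdm_features(
            np.full((5, 5), 3))
        assert (busy, contrast, cmplx, strength) == (0.0, 0.0, 0.0, 0.0)
        assert coarse == pytest.approx(1e12, rel=1e-6)

    def test_two_tone_hand_example(self):
        """4x4 two-tone patch agrees with the explicit neighbourhood
        enumeration."""
        qw = np.array([[0, 0, 1, 1],
                       [0, 1, 1, 1],
                       [0, 0, 1, 0],
                       [1, 1, 0, 0]])
        got = ngtdm_features(qw)
        want = oracles.ngtdm_bruteforce(qw)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for _ in range(30):
            qw = rng.integers(0, 5, size=(8, 8))
            np.testing.assert_allclose(ngtdm_features(qw),
                                       oracles.ngtdm_bruteforce(qw),
                                       rtol=1e-12, atol=1e-12)

    def test_noise_increases_busyness(self, rng):
        """Adding quantized noise of growing amplitude to a flat field
        strictly increases busyness."""
        base = np.full((9, 9), 8)
        flat_busy = ngtdm_features(base)[0]
        assert flat_busy == 0.0
        for seed in range(5):
            r = np.random.default_rng(seed)
            for amp in (1, 2, 4):
                noisy = base + r.integers(-amp, amp + 1, size=base.shape)
                assert ngtdm_features(noisy)[0] > flat_busy

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            ngtdm_features(np.zeros((2, 4), dtype=int))


class TestFractalDimension:
    def test_constant_image_slope_exactly_two(self):
        """Flat surface: N(s) = (M/s)^2 exactly, so the fitted dimension
        is 2."""
        w = np.full((60, 60), 9.0)
        logs = fd_features(w, scales=(2, 3, 4, 5), gray_range=0.0)
        for s, ln in zip((2, 3, 4, 5), logs):
            assert np.exp(ln) == pytest.approx((60 // s) ** 2, rel=1e-12)
        assert fd_slope(logs) == pytest.approx(2.0, abs=1e-12)

    def test_inclined_plane_near_two(self):
        """Oracle run of the box-counting recipe on a 64x64 ramp."""
        x = np.arange(64, dtype=float)
        plane = np.tile(x, (64, 1))
        logs = fd_features(plane, scales=(2, 3, 4, 5))
        want = [np.log(oracles.box_count_recipe(plane, s, 63.0))
                for s in (2, 3, 4, 5)]
        np.testing.assert_allclose(logs, want, rtol=1e-12)
        assert 2.0 <= fd_slope(logs) <= 2.1

    def test_noise_rougher_than_plane(self):
        x = np.arange(64, dtype=float)
        plane_fd = fd_slope(fd_features(np.tile(x, (64, 1))))
        for seed in range(10):
            noise = np.random.default_rng(seed).uniform(0, 63, (64, 64))
            assert fd_slope(fd_features(noise)) > plane_fd

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            fd_features(np.zeros((8, 8)), scales=(2, 3, 4, 5))


class TestQuantizeInvariance:
    def test_offset_invariance_of_quantized_features(self, rng):
        """GLCM/NGTDM/FD anchor quantization at min-max, so adding a
        constant offset changes nothing."""
        img = rng.uniform(0, 100, size=(16, 16))
        q1 = quantize(img, 16)
        q2 = quantize(img + 37.5, 16)
        np.testing.assert_array_equal(q1, q2)
        np.testing.assert_allclose(glcm_features(q1, 16),
                                   glcm_features(q2, 16))

    def test_flat_image_quantizes_to_zero(self):
        assert quantize(np.full((4, 4), 3.3), 8).max() == 0


@pytest.fixture(scope="module")
def stack_setup(sys_params):
    spec = PhantomSpec(
        tissue_sectors=((0.0, 180.0, FIBROUS, 1.2),
                        (180.0, 360.0, CALCIFIED, 1.2)),
        seed=3)
    pars = {FIBROUS: TissueOpticalParams(2.0, 16000.0, 2.0, 0.05),
            CALCIFIED: TissueOpticalParams(2.0, 16000.0, 1.0, 0.4)}
    img, labels, boundary = generate_phantom(spec, pars, sys_params)
    maps = attenuation_map(img, boundary, sys_params)
    rng = np.random.default_rng(0)
    rows, cols = np.nonzero(maps.roi)
    pick = rng.choice(rows.size, 800, replace=False)
    px = np.stack([rows[pick], cols[pick]], axis=1)
    stack = build_feature_stack(img, maps, boundary, pixels=px)
    return img, labels, boundary, stack


class TestFeatureStack:
    def test_feature_count_and_order(self, stack_setup):
        _, _, _, stack = stack_setup
        assert list(stack.columns[2:]) == list(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 25
        assert not stack.isna().any().any()

    def test_rp_x_zero_on_boundary(self, stack_setup):
        _, _, boundary, stack = stack_setup
        on_boundary = stack[stack["col"]
                            == np.asarray(boundary)[stack["row"]]]
        assert (on_boundary["x"] == 0).all()

    def test_texture_separates_sectors(self, stack_setup):
        """Two sectors with identical optics but texture amplitude 0.05 vs
        0.4 separate in mean GLCM contrast by far more than 3 pooled
        standard errors of the sector means."""
        _, labels, _, stack = stack_setup
        lab = labels.labels[stack["row"], stack["col"]]
        a = stack["contrast"][lab == FIBROUS]
        b = stack["contrast"][lab == CALCIFIED]
        pooled_se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) > 3 * pooled_se

    def test_feature_subset_selector(self):
        assert feature_subset("GLCM+RP") == (
            "correlation", "contrast", "dissimilarity", "energy", "entropy",
            "homogeneity", "max_probability", "x", "y")
        assert feature_subset("ALL") == FEATURE_NAMES
        with pytest.raises(KeyError):
            feature_subset("WAVELET+RP")

    def test_missing_optical_maps_error(self, stack_setup, sys_params):
        img, _, boundary, _ = stack_setup
        with pytest.raises(ValueError, match="optical"):
            build_feature_stack(img, None, boundary)
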