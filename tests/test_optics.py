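import numpy as np
import pytest

from octplaq import (PhantomSpec, SystemParams, TissueOpticalParams,
                     attenuation_map, backscatter_coefficient,
                     compensate_log_signal, confocal_psf, fit_attenuation,
                     generate_phantom, render_aline, rolloff)
from octplaq.io_oct import CALCIFIED, FIBROUS


class TestConfocalPsf:
    def test_maximum_at_beam_waist(self):
        assert confocal_psf(1.5, z0=1.5, zR=0.7) == 1.0

    def test_rayleigh_length_value(self):
        assert np.isclose(confocal_psf(2.0, z0=1.0, zR=1.0), 2 ** -0.5)

    def test_analytic_point(self):
        assert np.isclose(confocal_psf(2.0, z0=0.0, zR=1.0), 5 ** -0.5)

    def test_invalid_rayleigh_length(self):
        with pytest.raises(ValueError):
            confocal_psf(1.0, z0=0.0, zR=0.0)


class TestRolloff:
    def test_maximum_at_scan_centre(self):
        assert rolloff(0.8, zC=0.8, zW=2.0) == 1.0

    def test_half_width_value(self):
        assert np.isclose(rolloff(2.8, zC=0.8, zW=2.0), np.exp(-1.0))

    def test_symmetry_about_centre(self, rng):
        for d in rng.uniform(0, 3, size=10):
            assert np.isclose(rolloff(1.0 + d, 1.0, 1.7),
                              rolloff(1.0 - d, 1.0, 1.7), rtol=1e-14)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            rolloff(1.0, zC=0.0, zW=-1.0)


class TestCompensation:
    def test_inverts_forward_model_exactly(self, sys_params):
        """Dividing out T and s leaves a line of slope -mu_t through
        log I0 (machine precision, any valid parameter combination)."""
        mu, i0 = 3.7, 850.0
        r = np.arange(150) * sys_params.axial_spacing
        prof = (i0 * confocal_psf(r, sys_params.z0, sys_params.zR)
                * rolloff(r, sys_params.zC, sys_params.zW) * np.exp(-mu * r))
        corr = compensate_log_signal(prof, sys_params)
        fit = fit_attenuation(corr, (0, 150), sys_params.axial_spacing)
        assert abs(fit.mu_t - mu) < 1e-9
        assert abs(fit.log_i0 - np.log(i0)) < 1e-9
        assert fit.r2 == 1.0

    def test_neutral_parameters_reduce_to_log(self, neutral_sys):
        prof = np.linspace(10.0, 5.0, 50)
        corr = compensate_log_signal(prof, neutral_sys)
        np.testing.assert_allclose(corr, np.log(prof), atol=1e-9)

    def test_zero_pixel_excluded_not_fatal(self, neutral_sys):
        prof = np.full(30, 100.0)
        prof[10] = 0.0
        corr = compensate_log_signal(prof, neutral_sys)
        assert np.isnan(corr[10])
        fit = fit_attenuation(corr, (0, 30), neutral_sys.axial_spacing)
        assert abs(fit.mu_t) < 1e-12

    def test_all_masked_errors(self, neutral_sys):
        with pytest.raises(ValueError, match="no fit support"):
            compensate_log_signal(np.zeros(10), neutral_sys)


class TestFitAttenuation:
    def test_constant_profile_gives_zero_attenuation(self, neutral_sys):
        corr = np.log(np.full(20, 250.0))
        fit = fit_attenuation(corr, (0, 20), neutral_sys.axial_spacing)
        assert fit.mu_t == pytest.approx(0.0, abs=1e-12)
        assert fit.log_i0 == pytest.approx(np.log(250.0))

    def test_too_few_points_errors(self, neutral_sys):
        corr = np.array([1.0, np.nan, np.nan, 1.0, np.nan])
        with pytest.raises(ValueError, match="3"):
            fit_attenuation(corr, (0, 5), neutral_sys.axial_spacing)

    def test_estimator_consistency_under_speckle(self, neutral_sys):
        """The Monte-Carlo SD of mu_t-hat shrinks roughly as
        1/sqrt(window points)."""
        mu, i0 = 4.0, 1000.0
        rng = np.random.default_rng(3)
        sds = []
        for npts in (25, 100):
            est = []
            for _ in range(300):
                labels = np.full(npts, FIBROUS)
                prof = render_aline(
                    labels, {FIBROUS: TissueOpticalParams(mu, i0)},
                    neutral_sys, L=4, rng=rng)
                corr = compensate_log_signal(prof, neutral_sys)
                est.append(fit_attenuation(corr, (0, npts),
                                           neutral_sys.axial_spacing).mu_t)
            sds.append(np.std(est))
        # 4x the points: SD should drop by ~sqrt(4)*sqrt(x-spread gain)
        assert sds[1] < sds[0] / 2


class TestBackscatter:
    def test_arithmetic(self):
        res = backscatter_coefficient(np.log(1000.0), 500.0)
        assert res.mu_b == pytest.approx(2.0)

    def test_unit_case(self):
        assert backscatter_coefficient(np.log(77.0), 77.0).mu_b == \
            pytest.approx(1.0)

    def test_inverse_scaling(self):
        a = backscatter_coefficient(np.log(100.0), 50.0).mu_b
        b = backscatter_coefficient(np.log(100.0), 25.0).mu_b
        assert b == pytest.approx(2 * a)

    def test_nonpositive_i_prime_rejected(self):
        with pytest.raises(ValueError):
            backscatter_coefficient(1.0, 0.0)


class TestAttenuationMap:
    def test_two_sector_recovery_noiseless(self, sys_params):
        """Noiseless two-tissue phantom: per-sector median mu_t within 1%
        of the simulated truth."""
        spec = PhantomSpec(
            tissue_sectors=((0.0, 180.0, FIBROUS, 1.2),
                            (180.0, 360.0, CALCIFIED, 1.2)),
            speckle_looks=None, seed=0)
        pars = {FIBROUS: TissueOpticalParams(2.0, 16000.0),
                CALCIFIED: TissueOpticalParams(6.0, 16000.0)}
        img, labels, boundary = generate_phantom(spec, pars, sys_params)
        maps = attenuation_map(img, boundary, sys_params)
        for lab, mu_true in ((FIBROUS, 2.0), (CALCIFIED, 6.0)):
            sel = (labels.labels == lab) & maps.roi
            med = np.nanmedian(maps.mu_t[sel])
            assert abs(med - mu_true) / mu_true < 0.01

    def test_roi_equals_analysis_band(self, sys_params):
        spec = PhantomSpec(speckle_looks=None, seed=1)
        img, _, boundary = generate_phantom(spec, None, sys_params)
        maps = attenuation_map(img, boundary, sys_params,
                               analysis_depth=1.0)
        depth_px = int(round(1.0 / sys_params.axial_spacing))
        for i in range(img.n_alines):
            band = np.zeros(img.n_depth, bool)
            band[boundary[i]:min(boundary[i] + depth_px, img.n_depth)] = True
            np.testing.assert_array_equal(maps.roi[i], band)

    def test_missing_boundary_errors(self, sys_params, three_sector_phantom):
        _, img, _, _ = three_sector_phantom
        with pytest.raises(ValueError, match="boundary"):
            attenuation_map(img, None, sys_params)
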