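import numpy as np
import numpy.testing as npt
import pytest
from scipy import stats

from scatterlearn.features import (
    RadialCurve,
    characterize,
    enrich_curve,
    lowpass_filter,
    radial_density,
    scaled_gaussian_width,
    total_power,
)
from scatterlearn.simulator import OpticsConfig, SampleParams, render_pattern

_FILTER_STD = 7.0 / (2 * np.sqrt(2 * np.log(2)))  # kernel FWHM 7 px


class TestLowpassFilter:
    def test_constant_image_unchanged(self):
        img = np.full((50, 50), 3.7)
        npt.assert_allclose(lowpass_filter(img), img, rtol=1e-10)

    def test_impulse_response_is_gaussian_with_conserved_sum(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        out = lowpass_filter(img)
        npt.assert_allclose(out.sum(), 1.0, rtol=1e-6)
        # width of the response matches the kernel
        yy, xx = np.indices(out.shape)
        var = np.sum(out * ((yy - 50) ** 2)) / out.sum()
        npt.assert_allclose(np.sqrt(var), _FILTER_STD, rtol=0.05)

    def test_energy_conserved_on_random_image(self, rng):
        img = rng.random((100, 100))
        npt.assert_allclose(lowpass_filter(img).sum() / img.sum(), 1.0,
                            rtol=1e-6)

    def test_kernel_wider_than_image_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones((5, 5)), kernel_width=9)


class TestTotalPower:
    def test_hand_cases(self):
        assert total_power(np.ones((100, 100))) == 10_000
        assert total_power(np.zeros((10, 10))) == 0

    def test_equals_accepted_photon_count(self):
        sample = SampleParams(t=250, g=0.9, s_l=90)
        img = render_pattern(sample, OpticsConfig(n_photons=50_000), seed=21)
        assert total_power(img) == img.intensity.sum()
        assert total_power(img) <= img.meta["fates"]["transmitted_scattered"]


class TestRadialDensity:
    def test_normalized_symmetric_curve(self, gaussian_image):
        img, _ = gaussian_image
        curve = radial_density(img)
        assert curve.normalized
        npt.assert_allclose(curve.area, 1.0, atol=1e-3)
        npt.assert_allclose(curve.values, curve.values[::-1])
        npt.assert_allclose(curve.radii, -curve.radii[::-1])

    def test_gaussian_profile_recovered(self, gaussian_image):
        # angular averaging of an isotropic Gaussian gives a 1-D Gaussian
        # of the same width
        img, w = gaussian_image
        curve = radial_density(img)
        second = np.trapezoid(curve.radii**2 * curve.values, curve.radii)
        npt.assert_allclose(np.sqrt(second), w, rtol=0.03)

    def test_central_mass_concentrates_at_small_radius(self):
        img = np.zeros((101, 101))
        img[50, 50] = 5.0
        curve = radial_density(img, center=(50, 50))
        assert curve.values[np.argmin(np.abs(curve.radii))] > 0
        assert np.all(curve.values[np.abs(curve.radii) > 1] == 0)

    def test_zero_power_image_rejected(self):
        with pytest.raises(ValueError):
            radial_density(np.zeros((20, 20)))


class TestEnrichCurve:
    @staticmethod
    def _gauss_curve(noise_sd=0.0, seed=0):
        r = np.arange(-50.0, 51.0)
        v = stats.norm.pdf(r, scale=12.0)
        if noise_sd:
            v = v + np.random.default_rng(seed).normal(0, noise_sd, v.size)
        v = v / np.trapezoid(v, r)
        return RadialCurve(r, v, normalized=True)

    def test_noiseless_curve_near_interpolated(self):
        curve = self._gauss_curve()
        enriched, nugget = enrich_curve(curve)
        assert nugget <= 1e-4
        # compare regressor mean with the input samples at the input radii
        pred = np.interp(curve.radii, enriched.radii, enriched.values)
        dev = np.abs(pred - curve.values)
        assert dev.max() < 0.01 * curve.values.max()

    def test_nugget_grows_with_injected_noise(self):
        _, nugget_clean = enrich_curve(self._gauss_curve())
        _, nugget_noisy = enrich_curve(self._gauss_curve(noise_sd=0.001))
        assert nugget_noisy >= 10 * nugget_clean

    def test_heavy_scattering_noisier_than_weak(self):
        # photon-starved diffuse image vs photon-rich forward image
        optics = OpticsConfig(n_photons=100_000)
        heavy = render_pattern(SampleParams(t=600, g=0.7, s_l=30), optics,
                               seed=4)
        weak = render_pattern(SampleParams(t=200, g=0.93, s_l=120), optics,
                              seed=4)
        f_heavy = characterize(heavy)
        f_weak = characterize(weak)
        assert f_heavy.nugget_1d > f_weak.nugget_1d
        # Fig-4-style ordering of the features themselves
        assert f_heavy.sigma > f_weak.sigma
        assert f_heavy.p < f_weak.p

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            enrich_curve(RadialCurve([0, 1, 2], [1, 1, 1], normalized=True))


class TestScaledGaussianWidth:
    def test_second_moment_of_gaussian_pdf(self):
        r = np.linspace(-80, 80, 2001)
        curve = RadialCurve(r, stats.norm.pdf(r, scale=10.0), normalized=True)
        assert scaled_gaussian_width(curve, p=1.0) == pytest.approx(10.0,
                                                                    abs=0.1)
        assert scaled_gaussian_width(curve, p=2.0) == pytest.approx(5.0,
                                                                    abs=0.05)

    def test_zero_power_rejected(self):
        r = np.linspace(-5, 5, 11)
        curve = RadialCurve(r, np.ones(11) / 10, normalized=True)
        with pytest.raises(ValueError):
            scaled_gaussian_width(curve, p=0.0)


class TestCharacterize:
    def test_deterministic(self, gaussian_image):
        img, _ = gaussian_image
        f1 = characterize(img)
        f2 = characterize(img)
        assert (f1.p, f1.sigma) == (f2.p, f2.sigma)

    def test_scale_property(self, gaussian_image):
        # c·image: p scales by c, σ by 1/c (normalized shape is invariant)
        img, _ = gaussian_image
        base = characterize(img)
        scaled = characterize(3.0 * img)
        npt.assert_allclose(scaled.p, 3.0 * base.p, rtol=1e-9)
        npt.assert_allclose(scaled.sigma, base.sigma / 3.0, rtol=0.02)

    def test_uniform_perturbation_shifts_sigma_through_power_only(
        self, gaussian_image
    ):
        img, _ = gaussian_image
        base = characterize(img)
        bumped = characterize(1.01 * img)
        npt.assert_allclose(bumped.sigma, base.sigma / 1.01, rtol=0.02)

    def test_p_sigma_negatively_correlated_across_doe(self, small_training):
        feat = small_training.features
        rho = stats.spearmanr(feat.p, feat.sigma).statistic
        assert rho < 0

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            characterize(np.zeros((50, 50)))
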