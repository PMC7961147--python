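"""Fiber-network constitutive model: distributions, stress integral, fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from morphomech import mechanics, synthetic

PARAMS = mechanics.FiberModelParams(
    A=0.1, B=40.0, k_matrix=2.0, sigma0=35.0, sigma_inf=10.0, alpha=20.0, theta0=0.0
)


class TestSigmaOfStrain:
    def test_closed_form_value(self):
        p = mechanics.FiberModelParams(0.1, 40, 2, 35.0, 10.0, 20.0)
        assert mechanics.sigma_of_strain(0.05, p) == pytest.approx(
            35.0 * math.exp(-1.0) + 10.0, abs=1e-9
        )

    def test_zero_strain_limit(self):
        assert mechanics.sigma_of_strain(0.0, PARAMS) == pytest.approx(45.0)

    def test_no_reorganization_when_alpha_zero(self):
        p = mechanics.FiberModelParams(0.1, 40, 2, 35.0, 10.0, 0.0)
        eps = np.linspace(0, 0.2, 7)
        np.testing.assert_allclose(mechanics.sigma_of_strain(eps, p), 45.0)

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            mechanics.sigma_of_strain(-0.01, PARAMS)

    def test_monotone_nonincreasing(self):
        eps = np.linspace(0, 0.3, 50)
        sig = mechanics.sigma_of_strain(eps, PARAMS)
        assert np.all(np.diff(sig) <= 0)


class TestAngleDistribution:
    @pytest.mark.parametrize("sigma_inf", [1.0, 5.0, 20.0, 60.0, 90.0])
    def test_unit_integral(self, sigma_inf):
        p = mechanics.FiberModelParams(0.1, 40, 2, 0.0, sigma_inf, 0.0, theta0=15.0)
        val, _ = quad(
            lambda th: mechanics.angle_distribution(np.array([th]), 0.0, p)[0],
            -90.0, 90.0, limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_about_preferred_angle(self):
        p = mechanics.FiberModelParams(0.1, 40, 2, 35.0, 10.0, 20.0, theta0=10.0)
        for delta in (5.0, 20.0, 40.0):
            left = mechanics.angle_distribution(np.array([10.0 - delta]), 0.0, p)
            right = mechanics.angle_distribution(np.array([10.0 + delta]), 0.0, p)
            assert left[0] == pytest.approx(right[0], rel=1e-12)

    def test_strain_tightens_distribution(self):
        peak0 = mechanics.angle_distribution(np.array([0.0]), 0.0, PARAMS)[0]
        peak9 = mechanics.angle_distribution(np.array([0.0]), 0.09, PARAMS)[0]
        assert peak9 > peak0

    def test_grid_bounds_enforced(self):
        with pytest.raises(ValueError):
            mechanics.angle_distribution(np.array([95.0]), 0.0, PARAMS)


class TestPredictStress:
    def test_zero_strain_gives_zero_stress(self):
        c = mechanics.predict_stress(np.array([0.0]), PARAMS)
        assert c.stress_mpa[0] == 0.0

    def test_matrix_only_limit_exact(self):
        p = mechanics.FiberModelParams(0.0, 40, 2.0, 35, 10, 20)
        grid = np.linspace(0, 0.1, 11)
        c = mechanics.predict_stress(grid, p)
        np.testing.assert_allclose(c.stress_mpa, 2.0 * grid)

    def test_default_steps_match_fine_grid_oracle(self):
        grid = np.array([0.0, 0.03, 0.06, 0.09])
        coarse = mechanics.predict_stress(grid, PARAMS)
        fine = mechanics.predict_stress(grid, PARAMS, theta_step=0.1, eps_step=1e-5)
        rel = abs(coarse.stress_mpa[-1] - fine.stress_mpa[-1]) / fine.stress_mpa[-1]
        assert rel < 0.01

    def test_monotone_in_parameters_and_strain(self):
        grid = np.linspace(0, 0.09, 10)
        base = mechanics.predict_stress(grid, PARAMS).stress_mpa
        assert np.all(np.diff(base) > 0)
        up_a = mechanics.predict_stress(
            grid, mechanics.FiberModelParams(0.2, 40, 2, 35, 10, 20)
        ).stress_mpa
        up_k = mechanics.predict_stress(
            grid, mechanics.FiberModelParams(0.1, 40, 4, 35, 10, 20)
        ).stress_mpa
        assert np.all(up_a[1:] > base[1:])
        assert np.all(up_k[1:] > base[1:])

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            mechanics.predict_stress(np.array([0.0, 0.05, 0.03]), PARAMS)


class TestFitOrganization:
    def test_noiseless_self_consistency(self):
        hists = synthetic.generate_angle_histograms(
            PARAMS, strains=(0.0, 0.02, 0.05, 0.09), noise_cv=0.0
        )
        org = mechanics.fit_organization(hists)
        assert org.sigma0 == pytest.approx(35.0, rel=0.01)
        assert org.sigma_inf == pytest.approx(10.0, rel=0.01)
        assert org.alpha == pytest.approx(20.0, rel=0.01)
        assert org.theta0 == pytest.approx(0.0, abs=0.5)

    def test_single_strain_is_unidentifiable(self):
        hists = synthetic.generate_angle_histograms(PARAMS, strains=(0.03,))
        with pytest.raises(ValueError, match="identifiab"):
            mechanics.fit_organization(hists)

    def test_noisy_recovery_median_over_seeds(self):
        # simulation-refit study: 5% bin noise, 4 strains, 20 seeds
        err0, errinf = [], []
        for seed in range(20):
            hists = synthetic.generate_angle_histograms(
                PARAMS, strains=(0.0, 0.03, 0.06, 0.09), noise_cv=0.05, seed=seed
            )
            org = mechanics.fit_organization(hists)
            err0.append(abs(org.sigma0 - 35.0) / 35.0)
            errinf.append(abs(org.sigma_inf - 10.0) / 10.0)
        assert np.median(err0) < 0.15
        assert np.median(errinf) < 0.15


class TestFitStressParams:
    def test_noiseless_refit_recovers_parameters(self):
        df = synthetic.generate_stress_strain(PARAMS, 0.06, 61, noise_cv=0.0)
        curve = mechanics.StressStrainCurve(
            df["strain"].to_numpy(), df["stress_mpa"].to_numpy()
        )
        fit = mechanics.fit_stress_params(curve, PARAMS)
        assert fit.r_squared >= 0.999
        assert fit.A == pytest.approx(0.1, rel=0.02)
        assert fit.B == pytest.approx(40.0, rel=0.02)
        assert fit.k_matrix == pytest.approx(2.0, rel=0.02)

    def test_noisy_curve_keeps_good_fit(self):
        df = synthetic.generate_stress_strain(PARAMS, 0.06, 61, noise_cv=0.02, seed=5)
        curve = mechanics.StressStrainCurve(
            df["strain"].to_numpy(), df["stress_mpa"].to_numpy()
        )
        fit = mechanics.fit_stress_params(curve, PARAMS)
        assert fit.r_squared >= 0.9

    def test_matrix_only_slope_recovered(self):
        p = mechanics.FiberModelParams(0.0, 40.0, 2.0, 35.0, 10.0, 20.0)
        grid = np.linspace(0, 0.06, 31)
        curve = mechanics.StressStrainCurve(grid, 2.0 * grid)
        fit = mechanics.fit_stress_params(curve, p)
        assert fit.k_matrix == pytest.approx(2.0, abs=0.01)

    def test_constant_stress_rejected(self):
        grid = np.linspace(0, 0.06, 20)
        with pytest.raises(ValueError, match="degenerate"):
            mechanics.fit_stress_params(
                mechanics.StressStrainCurve(grid, np.ones_like(grid)), PARAMS
            )


class TestOrientationFromImage:
    @staticmethod
    def stripes(angle_deg, shape=(256, 256), period=12.0):
        y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        rad = math.radians(angle_deg)
        phase = -math.sin(rad) * x + math.cos(rad) * (-y)
        return np.sin(2 * math.pi * phase / period)

    def test_stripe_orientation_recovered(self):
        h = mechanics.orientation_from_image(self.stripes(30.0), n_bins=45)
        mode = h.theta_deg[np.argmax(h.frequency)]
        assert abs(mode - 30.0) <= 4.0  # one 4-degree bin

    def test_rotation_equivariance(self):
        h0 = mechanics.orientation_from_image(self.stripes(-20.0), n_bins=45)
        h1 = mechanics.orientation_from_image(self.stripes(25.0), n_bins=45)
        m0 = h0.theta_deg[np.argmax(h0.frequency)]
        m1 = h1.theta_deg[np.argmax(h1.frequency)]
        assert abs((m1 - m0) - 45.0) <= 4.0

    def test_isotropic_noise_is_flat(self):
        hists = []
        for seed in range(10):
            img = np.random.default_rng(seed).normal(size=(256, 256))
            hists.append(mechanics.orientation_from_image(img, n_bins=45).frequency)
        mean_hist = np.mean(hists, axis=0)
        assert mean_hist.max() / mean_hist.min() < 2.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            mechanics.orientation_from_image(np.ones((128, 128)))

    def test_histogram_normalized(self):
        h = mechanics.orientation_from_image(self.stripes(10.0))
        assert np.trapezoid(h.frequency, h.theta_deg) == pytest.approx(1.0, abs=1e-9)
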