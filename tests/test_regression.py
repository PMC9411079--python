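"""Weighted log-parabola regression: exactness, rejection filters,
error propagation, equivariances, and blocked-solve equivalence."""

import math

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from dqcentroid import (
    backtransform,
    compute_weights,
    fit_profiles,
    generate_spectrum,
    isolate_profiles,
)
from dqcentroid.regression import RegressionResult, RejectRecord

from conftest import make_spectrum


def fit_points(mz, intensity, **kwargs):
    """Fit a single zero-padded profile built from raw points."""
    step = float(np.min(np.diff(mz)))
    full_mz = np.concatenate([[mz[0] - step], mz, [mz[-1] + step]])
    full_int = np.concatenate([[0.0], intensity, [0.0]])
    (profile,) = isolate_profiles(make_spectrum(full_int, mz=full_mz))
    (result,) = fit_profiles([profile], **kwargs)
    return result


class TestWeights:
    def test_squared_fractions(self):
        np.testing.assert_allclose(
            compute_weights(np.array([1.0, 1.0, 2.0])), [0.0625, 0.0625, 0.25]
        )

    def test_single_point_and_symmetry(self):
        np.testing.assert_allclose(compute_weights(np.array([5.0])), [1.0])
        for c in (0.5, 3.0, 1e6):
            np.testing.assert_allclose(
                compute_weights(np.full(4, c)), np.full(4, 0.0625)
            )

    def test_scale_invariant_any_power(self):
        intensity = np.array([2.0, 7.0, 3.0])
        for p in (0.0, 1.0, 2.0, 3.5):
            np.testing.assert_allclose(
                compute_weights(intensity, p), compute_weights(10.0 * intensity, p)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([]))


class TestFit:
    def test_log_of_gaussian_is_exact_parabola(self):
        x = np.arange(-3.0, 4.0)
        intensity = 1000.0 * np.exp(-(x**2) / 2.0)
        result = fit_points(x + 500.0, intensity)  # x_shift lands on the apex
        assert isinstance(result, RegressionResult)
        np.testing.assert_allclose(
            result.beta, [math.log(1000.0), 0.0, -0.5], atol=1e-9
        )
        assert result.mse < 1e-18
        assert result.dof == 4

    def test_four_point_recovery_matches_nonlinear_oracle(self):
        x = np.array([199.997, 199.999, 200.001, 200.003])
        x0, sigma, height = 200.0, 0.002, 1e6
        intensity = height * np.exp(-0.5 * ((x - x0) / sigma) ** 2)
        result = fit_points(x, intensity)
        peak = backtransform(result)
        assert abs(peak.x0 - x0) / x0 <= 1e-9
        assert abs(peak.sigma - sigma) / sigma <= 1e-9
        # independent iterative non-linear oracle, exact on noiseless data
        popt, _ = scipy.optimize.curve_fit(
            lambda x, m, s, a: a * np.exp(-0.5 * ((x - m) / s) ** 2),
            x, intensity, p0=(199.999, 0.001, intensity.max()),
        )
        assert abs(peak.x0 - popt[0]) <= 1e-6 * x0
        assert abs(peak.sigma - popt[1]) <= 1e-6 * sigma

    def test_three_points_rejected_without_fitting(self):
        spectrum = make_spectrum([0, 2, 9, 2, 0])
        (profile,) = isolate_profiles(spectrum)
        (result,) = fit_profiles([profile])
        assert isinstance(result, RejectRecord)
        assert result.reason == "min_points"

    def test_result_order_matches_input_order(self):
        truth = generate_spectrum(n_peaks=10, seed=5)
        profiles = isolate_profiles(truth.spectrum)
        results = fit_profiles(profiles)
        assert all(r.profile is p for r, p in zip(results, profiles))

    def test_dof_is_n_minus_3(self, random_truth):
        for result in fit_profiles(isolate_profiles(random_truth.spectrum)):
            assert result.dof == result.profile.n_points - 3 >= 1

    def test_cov_symmetric_positive_semidefinite(self):
        truth = generate_spectrum(n_peaks=20, noise_cv=0.02, seed=11)
        for result in fit_profiles(isolate_profiles(truth.spectrum)):
            if isinstance(result, RejectRecord):
                continue
            np.testing.assert_allclose(result.cov_beta, result.cov_beta.T, atol=1e-25)
            assert np.all(np.linalg.eigvalsh(result.cov_beta) > -1e-12)
            assert result.mse >= 0

    def test_nrmse_is_rms_over_mean_log_intensity(self):
        x = np.array([-1.5, -0.5, 0.5, 1.5, 2.5])
        intensity = 100.0 * np.exp(-0.5 * x**2) * np.exp([0.01, -0.02, 0.015, 0.0, -0.01])
        result = fit_points(x + 300.0, intensity)
        assert result.nrmse == pytest.approx(
            math.sqrt(result.mse) / np.mean(np.log(intensity))
        )


class TestBacktransform:
    def test_direct_substitution(self):
        result = RegressionResult(
            profile=None, beta=np.array([math.log(100.0), 0.0, -0.5]),
            cov_beta=np.zeros((3, 3)), mse=0.0, dof=4, nrmse=0.0, x_shift=0.0,
        )
        peak = backtransform(result)
        assert peak.x0 == 0.0
        assert peak.sigma == pytest.approx(1.0, rel=1e-15)
        assert peak.height == pytest.approx(100.0, rel=1e-12)
        assert peak.area == pytest.approx(100.0 * math.sqrt(2 * math.pi), rel=1e-12)

    def test_offcenter_parabola(self):
        result = RegressionResult(
            profile=None, beta=np.array([0.0, 2.0, -1.0]),
            cov_beta=np.zeros((3, 3)), mse=0.0, dof=1, nrmse=0.0, x_shift=0.0,
        )
        peak = backtransform(result)
        assert peak.x0 == pytest.approx(1.0)
        assert peak.sigma == pytest.approx(math.sqrt(0.5))
        assert peak.height == pytest.approx(math.e)

    def test_upward_parabola_rejected(self):
        result = RegressionResult(
            profile="p", beta=np.array([1.0, 0.0, 0.1]),
            cov_beta=np.zeros((3, 3)), mse=0.0, dof=1, nrmse=0.0, x_shift=0.0,
        )
        reject = backtransform(result)
        assert isinstance(reject, RejectRecord)
        assert reject.reason == "beta2_nonneg"

    def test_zero_covariance_propagates_zero_errors(self):
        result = RegressionResult(
            profile=None, beta=np.array([1.0, 0.5, -0.25]),
            cov_beta=np.zeros((3, 3)), mse=0.0, dof=2, nrmse=0.0, x_shift=0.0,
        )
        peak = backtransform(result)
        assert peak.d_height == peak.d_sigma == peak.d_area == 0.0

    def test_area_error_combines_height_and_width_terms(self):
        # diagonal covariance makes the propagation analytic
        cov = np.diag([1e-4, 0.0, 1e-6])
        beta = np.array([math.log(50.0), 0.0, -0.5])
        result = RegressionResult(
            profile=None, beta=beta, cov_beta=cov, mse=1.0, dof=3, nrmse=0.0,
            x_shift=0.0,
        )
        peak = backtransform(result)
        sigma, height = 1.0, 50.0
        d_height = height * math.sqrt(1e-4)  # apex at 0: gradient (1, 0, 0)
        d_sigma = abs(1.0 / (4 * sigma * 0.25)) * math.sqrt(1e-6)
        expected = math.sqrt(2 * math.pi) * math.hypot(
            sigma * d_height, height * d_sigma
        )
        assert peak.d_height == pytest.approx(d_height, rel=1e-12)
        assert peak.d_sigma == pytest.approx(d_sigma, rel=1e-12)
        assert peak.d_area == pytest.approx(expected, rel=1e-12)


class TestProperties:
    @settings(deadline=None, max_examples=50)
    @given(
        sigma=st.floats(5e-4, 5e-3),
        x0=st.floats(150.0, 900.0),
        log_height=st.floats(3.0, 7.0),
        n=st.integers(4, 20),
    )
    def test_noiseless_recovery_exact(self, sigma, x0, log_height, n):
        offsets = np.linspace(-3 * sigma, 3 * sigma, n)
        height = 10.0**log_height
        intensity = height * np.exp(-0.5 * (offsets / sigma) ** 2)
        result = fit_points(x0 + offsets, intensity)
        peak = backtransform(result)
        assert result.mse <= 1e-18
        assert abs(peak.x0 - x0) / x0 <= 1e-9
        assert abs(peak.sigma - sigma) / sigma <= 1e-9
        assert abs(peak.height - height) / height <= 1e-9

    def test_scale_equivariance(self):
        x = np.linspace(-2.5, 2.5, 9)
        rng = np.random.default_rng(3)
        intensity = 1e4 * np.exp(-0.5 * x**2) * np.exp(rng.normal(0, 0.02, x.size))
        base = backtransform(fit_points(x + 400.0, intensity))
        scaled = backtransform(fit_points(x + 400.0, 7.5 * intensity))
        assert scaled.x0 == pytest.approx(base.x0, abs=1e-12)
        assert scaled.sigma == pytest.approx(base.sigma, rel=1e-12)
        assert scaled.height == pytest.approx(7.5 * base.height, rel=1e-9)
        assert scaled.area == pytest.approx(7.5 * base.area, rel=1e-9)

    def test_shift_equivariance(self):
        x = np.linspace(-2.5, 2.5, 9)
        rng = np.random.default_rng(4)
        intensity = 1e5 * np.exp(-0.5 * x**2) * np.exp(rng.normal(0, 0.02, x.size))
        base = backtransform(fit_points(x + 200.0, intensity))
        shifted = backtransform(fit_points(x + 450.0, intensity))
        assert shifted.x0 - base.x0 == pytest.approx(250.0, abs=1e-9)
        assert shifted.sigma == pytest.approx(base.sigma, rel=1e-9)
        assert shifted.height == pytest.approx(base.height, rel=1e-9)

    def test_blocked_solve_equals_per_profile(self):
        truth = generate_spectrum(n_peaks=40, noise_cv=0.01, seed=21)
        profiles = isolate_profiles(truth.spectrum)
        dense = fit_profiles(profiles, method="per_profile")
        blocked = fit_profiles(profiles, method="blocked")
        assert len(dense) == len(blocked)
        for a, b in zip(dense, blocked):
            np.testing.assert_allclose(b.beta, a.beta, rtol=1e-9)
            np.testing.assert_allclose(b.cov_beta, a.cov_beta, rtol=1e-9, atol=1e-30)
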