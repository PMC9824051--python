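"""Tip-profile sampling, Gaussian fitting, velocity, smoothing, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipkinetics import synthetic as syn
from tipkinetics.exceptions import FitError, ParameterError
from tipkinetics.kinematics import (
    IntensityProfile,
    aggregate_distribution,
    compute_velocity,
    fit_gaussian,
    sample_tip_profile,
    smooth_and_detrend,
)
from tipkinetics.models import gaussian_peak
from tipkinetics.segmentation import GrowthTrajectory


def _straight_trajectory(row=32.0, n=200, pixel_size=0.2):
    pts = np.stack([np.full(n, row), np.arange(n, dtype=float)], axis=1)
    return GrowthTrajectory(points=pts, arclength=np.arange(n) * pixel_size, pixel_size=pixel_size)


class TestSampleTipProfile:
    def test_constant_image_gives_constant_profile(self):
        traj = _straight_trajectory()
        prof = sample_tip_profile(np.full((64, 200), 7.0), traj, s_tip=20.0)
        np.testing.assert_allclose(prof.I, 7.0)

    def test_width_irrelevant_on_transversally_constant_image(self):
        traj = _straight_trajectory()
        img = np.tile(np.linspace(0, 100, 200)[None, :], (64, 1))
        p1 = sample_tip_profile(img, traj, s_tip=20.0, width_px=1)
        p3 = sample_tip_profile(img, traj, s_tip=20.0, width_px=3)
        np.testing.assert_allclose(p1.I, p3.I, atol=1e-9)

    def test_matches_rendered_apex_cross_section(self):
        geom = syn.TubeGeometry(psf_sigma=0.0, image_shape=(64, 200))
        tip, sig = 30.0, 0.5
        frame = syn.render_frame(tip, sig, geom)
        traj = _straight_trajectory(row=32.0, pixel_size=geom.pixel_size)
        prof = sample_tip_profile(frame, traj, s_tip=tip, half_window_um=3.0)
        expected = geom.background + geom.wall_peak_intensity * np.exp(
            -((prof.s - tip) ** 2) / (2 * sig**2)
        )
        assert np.abs(prof.I - expected).max() <= 0.02 * geom.wall_peak_intensity

    def test_window_outside_image_raises(self):
        traj = _straight_trajectory()
        from tipkinetics.exceptions import ProfileError

        with pytest.raises(ProfileError):
            sample_tip_profile(np.zeros((64, 200)), traj, s_tip=41.0, half_window_um=3.0)


class TestFitGaussian:
    def test_exact_samples_recovered_to_machine_precision(self):
        s = np.linspace(0, 20, 61)
        I = gaussian_peak(s, 100.0, 10.0, 2.0, 5.0)
        fit = fit_gaussian(IntensityProfile(s=s, I=I))
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.center == pytest.approx(10.0, rel=1e-6)
        assert fit.sigma == pytest.approx(2.0, rel=1e-6)
        assert fit.baseline == pytest.approx(5.0, rel=1e-6)

    def test_flat_profile_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian(IntensityProfile(s=np.arange(10.0), I=np.full(10, 3.0)))

    def test_noisy_sigma_unbiased_and_se_matches_grid_oracle(self, rng):
        """Mean fitted sigma within 2% of truth; SE agrees with an
        independent grid-search fit of the same noisy draws within 20%."""
        s = np.linspace(0, 20, 61)
        clean = gaussian_peak(s, 100.0, 10.0, 2.0, 5.0)
        n_rep = 300
        sig_fit = np.empty(n_rep)
        sig_grid = np.empty(n_rep)
        mus = np.linspace(9.0, 11.0, 41)
        sigmas = np.linspace(1.5, 2.5, 81)
        # design matrices for linear (a, b) given (mu, sigma)
        for r in range(n_rep):
            y = clean + rng.normal(0, 5.0, len(s))
            sig_fit[r] = fit_gaussian(IntensityProfile(s=s, I=y)).sigma
            best = (np.inf, None)
            for mu in mus:
                for sg in sigmas:
                    g = np.exp(-((s - mu) ** 2) / (2 * sg**2))
                    X = np.stack([g, np.ones_like(s)], axis=1)
                    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                    rss = float(res[0]) if len(res) else float(np.sum((X @ coef - y) ** 2))
                    if rss < best[0]:
                        best = (rss, sg)
            sig_grid[r] = best[1]
        assert sig_fit.mean() == pytest.approx(2.0, rel=0.02)
        assert sig_fit.std(ddof=1) == pytest.approx(sig_grid.std(ddof=1), rel=0.2)


class TestVelocity:
    def test_linear_positions_give_constant_velocity(self):
        v = compute_velocity(np.arange(50) * 0.2, dt=1.0)
        np.testing.assert_allclose(v, 0.2, atol=1e-12)

    def test_constant_positions_give_zero(self):
        np.testing.assert_allclose(compute_velocity(np.full(10, 3.0), 1.0), 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        A, T, dt = 1.5, 40.0, 1.0
        t = np.arange(0, 200, dt)
        omega = 2 * np.pi / T
        x = A * np.sin(omega * t)
        v = compute_velocity(x, dt)
        bound = A * omega**3 * dt**2 / 6
        assert np.abs(v[1:-1] - A * omega * np.cos(omega * t[1:-1])).max() <= bound * 1.01

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=3, max_value=60), st.integers(min_value=0, max_value=2**31 - 1))
    def test_velocity_integrates_back_to_net_displacement(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n).cumsum()
        v = compute_velocity(x, dt=0.5)
        net = np.trapezoid(v, dx=0.5)
        assert net == pytest.approx(x[-1] - x[0], abs=1e-9)


class TestSmoothing:
    def test_constant_series_maps_to_zero(self):
        np.testing.assert_allclose(smooth_and_detrend(np.full(100, 4.2)), 0.0, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_and_detrend(np.arange(50.0), window=10)

    def test_output_mean_is_zero(self, rng):
        out = smooth_and_detrend(rng.normal(size=500), window=11)
        assert abs(out.mean()) < 1e-12

    def test_white_noise_variance_reduced_by_window(self, rng):
        x = rng.normal(size=10_000)
        out = smooth_and_detrend(x, window=11)
        assert out[20:-20].std() == pytest.approx(1 / np.sqrt(11), rel=0.1)

    def test_sinusoid_attenuated_by_dirichlet_factor(self):
        T, dt, M = 40.0, 1.0, 11
        t = np.arange(0, 400, dt)
        x = np.sin(2 * np.pi * t / T)
        out = smooth_and_detrend(x, window=M)
        gain = abs(np.sin(M * np.pi * dt / T) / (M * np.sin(np.pi * dt / T)))
        # fit amplitude on interior samples to avoid edge-truncation effects
        inner = slice(M, len(t) - M)
        basis = np.stack([np.sin(2 * np.pi * t / T), np.cos(2 * np.pi * t / T)], axis=1)
        coef, *_ = np.linalg.lstsq(basis[inner], out[inner], rcond=None)
        assert np.hypot(*coef) == pytest.approx(gain, rel=0.02)


class TestAggregateDistribution:
    def test_identical_tubes_equal_single_histogram(self, rng):
        x = rng.normal(size=200)
        edges = np.linspace(-3, 3, 20)
        single, _ = np.histogram(x, bins=edges, density=True)
        agg = aggregate_distribution([x, x, x], edges)
        np.testing.assert_allclose(agg, single)

    def test_disjoint_single_bins_average_half_half(self):
        edges = np.array([0.0, 1.0, 2.0])
        agg = aggregate_distribution([np.full(5, 0.5), np.full(5, 1.5)], edges)
        np.testing.assert_allclose(agg, [0.5, 0.5])

    def test_aggregate_integrates_to_one(self, rng):
        edges = np.linspace(0.1, 0.5, 21)  # support of 0.3 + 0.2 sin
        series = [0.3 + 0.2 * np.sin(2 * np.pi * rng.random(240)) for _ in range(20)]
        agg = aggregate_distribution(series, edges)
        assert np.sum(agg * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)
        # sinusoid value density concentrates near the extremes (arcsine shape)
        assert agg[0] > agg[len(agg) // 2] and agg[-2] > agg[len(agg) // 2]

    def test_all_empty_is_error(self):
        with pytest.raises(ParameterError):
            aggregate_distribution([[], []], np.linspace(0, 1, 5))
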