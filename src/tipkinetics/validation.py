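"""End-to-end recovery benchmarks on synthetic data with known ground truth.

The study's raw microscopy is not deposited, so the pipeline is validated by
parameter recovery: simulate cohorts under the documented study conditions
(oscillation period 40 s, 1 s frames, 240 s movies, SNR 10, thickness phase
leads of ~17-23 s), run the full measurement chain, and compare the
recovered quantities with the generator's truth.  Each function returns
plain floats so callers can assert or report them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import rotate as sk_rotate

from . import synthetic as syn
from .correlation import autocorrelation, cross_correlation
from .io import RunConfig
from .pipeline import analyze_stack, correlate_traces
from .profiles import compare_groups, fit_logistic4
from .segmentation import extract_trajectory, segment_frame, time_projection, tube_length
from .kinematics import smooth_and_detrend

# Study conditions for the oscillation benchmarks: 40 s period, 1 s frames,
# 240 s movies, wall-peak SNR 10 against Gaussian read noise.
STUDY_KINEMATICS = dict(v0=0.3, Av=0.2, w0=0.5, Aw=0.15, T=40.0, duration=240.0, dt=1.0)
STUDY_SNR = 10.0


def _render_cohort(delta: float, n_tubes: int, rng: np.random.Generator):
    geom = syn.TubeGeometry(
        noise_gaussian_sd=syn.TubeGeometry().wall_peak_intensity / STUDY_SNR
    )
    for _ in range(n_tubes):
        kp = syn.KinematicsParams(delta=delta, **STUDY_KINEMATICS)
        truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
        yield syn.render_stack(truth, geom, seed=int(rng.integers(2**31)))


def lag_recovery(deltas=(23.0, 17.0), n_tubes: int = 10, seed: int = 0) -> dict:
    """Full-pipeline cross-correlation peak lags for each thickness lead.

    Renders ``n_tubes`` noisy movies per condition, runs segmentation ->
    trajectory -> Gaussian tip/thickness tracking -> smoothing -> per-tube
    cross-correlation -> cohort averaging, and returns
    ``{delta: (recovered lag, SEM)}``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for delta in deltas:
        traces = [
            analyze_stack(stack).trace for stack in _render_cohort(delta, n_tubes, rng)
        ]
        corr = correlate_traces(traces, RunConfig(max_lag_s=60.0))
        out[delta] = (corr["cross_peak"].lag_s, corr["cross_peak"].uncertainty_s)
    return out


def thickness_calibration(
    n_frames: int = 100, sigma_true: float = 0.5, pixel_size: float = 0.1, seed: int = 0
) -> float:
    """Median relative wall-thickness error over independently rendered
    apical frames at the stated pixel size and SNR 10."""
    from .kinematics import fit_gaussian, sample_tip_profile
    from .segmentation import locate_tip

    geom = syn.TubeGeometry(
        pixel_size=pixel_size,
        image_shape=(120, 260),
        base_length=10.0,
        noise_gaussian_sd=syn.TubeGeometry().wall_peak_intensity / STUDY_SNR,
    )
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_frames):
        tip = 16.0 + rng.uniform(-1.0, 1.0)
        frame = syn.render_frame(tip, sigma_true, geom)
        from scipy.ndimage import gaussian_filter

        frame = gaussian_filter(frame, geom.psf_sigma / geom.pixel_size)
        frame = np.clip(
            frame + rng.normal(0.0, geom.noise_gaussian_sd, frame.shape), 0.0, None
        )
        mask = segment_frame(frame, geom.pixel_size)
        traj = extract_trajectory(
            mask, geom.pixel_size, base_hint=(geom.image_shape[0] / 2, 0), extend="both"
        )
        fit = fit_gaussian(
            sample_tip_profile(frame, traj, locate_tip(mask, traj), half_window_um=3.0)
        )
        errors.append(abs(fit.sigma - sigma_true) / sigma_true)
    return float(np.median(errors))


def correlation_oracle_deviation(n_series: int = 50, n: int = 200, seed: int = 0) -> float:
    """Max |vectorized - brute force| over random auto- and cross-correlations."""
    rng = np.random.default_rng(seed)
    k_max = 40
    worst = 0.0
    for _ in range(n_series):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        auto = autocorrelation(x, 1.0, float(k_max)).values
        cross = cross_correlation(x, y, 1.0, float(k_max)).values
        denom_a = np.sum(x * x)
        denom_c = np.sqrt(np.sum(x * x) * np.sum(y * y))
        for i, k in enumerate(range(-k_max, k_max + 1)):
            acc_a = 0.0
            acc_c = 0.0
            for t in range(n):
                if 0 <= t + k < n:
                    acc_a += x[t] * x[t + k]
                    acc_c += x[t] * y[t + k]
            worst = max(worst, abs(auto[i] - acc_a / denom_a), abs(cross[i] - acc_c / denom_c))
    return float(worst)


def smoothing_attenuation(T: float = 40.0, dt: float = 1.0, window: int = 11) -> tuple:
    """(measured, theoretical) amplitude gain of the running average on a
    period-T sinusoid; theory is the Dirichlet kernel value."""
    t = np.arange(0.0, 400.0, dt)
    x = np.sin(2 * np.pi * t / T)
    out = smooth_and_detrend(x, window=window)
    inner = slice(window, len(t) - window)
    basis = np.stack([np.sin(2 * np.pi * t / T), np.cos(2 * np.pi * t / T)], axis=1)
    coef, *_ = np.linalg.lstsq(basis[inner], out[inner], rcond=None)
    measured = float(np.hypot(*coef))
    theory = float(
        abs(np.sin(window * np.pi * dt / T) / (window * np.sin(np.pi * dt / T)))
    )
    return measured, theory


def roi_fraction_recovery(
    targets=(5.0, 15.0, 30.0, 60.0), n_seeds: int = 10, seed: int = 0
) -> float:
    """Mean absolute error (percentage points) between tabulated and realized
    covered-area fractions over generated puncta images."""
    from .roi import tabulate

    rng = np.random.default_rng(seed)
    errors = []
    for target in targets:
        for _ in range(n_seeds):
            img, realized, _ = syn.generate_roi_image(
                (100, 100), target, 3, seed=int(rng.integers(2**31)), noise_sd=2.0
            )
            table = tabulate(img, {"roi": np.ones((100, 100), bool)})
            errors.append(abs(table.area_fraction_pct.iloc[0] - realized))
    return float(np.mean(errors))


def logistic_recovery(n_tubes: int = 20, shift_um: float = 3.0, seed: int = 0) -> dict:
    """Two-cohort 4PL recovery under the stated noise.

    Control truth x_mid = 8 um, scale = 2 um; the second cohort's inflection
    is shifted ``shift_um`` toward the tip.  Returns group means and the
    Welch p-value for the shift.
    """
    x = np.arange(0.0, 30.1, 0.25)
    base = dict(lower=10.0, upper=100.0, x_mid=8.0, scale=2.0)
    jitter = {"x_mid": 0.8, "scale": 0.2, "upper": 10.0}
    rng = np.random.default_rng(seed)

    def cohort(x_mid, name):
        params = dict(base, x_mid=x_mid)
        profiles, _ = syn.generate_profile_samples(
            "logistic4", params, x, noise_sd=5.0, n_tubes=n_tubes,
            seed=int(rng.integers(2**31)), jitter=jitter,
        )
        fits, _ = fit_logistic4([(x, p) for p in profiles])
        return fits.assign(group=name)

    control = cohort(8.0, "control")
    treated = cohort(8.0 - shift_um, "treated")
    table = compare_groups(pd.concat([control, treated], ignore_index=True))
    xm = table[table.parameter == "x_mid"].set_index("group")
    sc = table[table.parameter == "scale"].set_index("group")
    return {
        "x_mid_control": float(xm.loc["control", "mean"]),
        "scale_control": float(sc.loc["control", "mean"]),
        "x_mid_treated": float(xm.loc["treated", "mean"]),
        "shift_p_value": float(xm.loc["treated", "p_vs_control"]),
    }


def geometry_invariance(seed: int = 0) -> dict:
    """Rotation invariance of tube length and centerline accuracy."""
    kp = syn.KinematicsParams(**STUDY_KINEMATICS, delta=20.0)
    geom = syn.TubeGeometry(image_shape=(160, 560))
    truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
    frame = syn.render_stack(truth, geom, seed=seed).frames[-1]
    mask = segment_frame(frame, geom.pixel_size)
    L0 = tube_length(mask, geom.pixel_size)
    L90 = tube_length(np.rot90(mask), geom.pixel_size)
    f30 = sk_rotate(frame, 30, resize=True, preserve_range=True, order=1, cval=frame.min())
    L30 = tube_length(segment_frame(f30, geom.pixel_size), geom.pixel_size)
    traj = extract_trajectory(
        mask, geom.pixel_size, base_hint=(geom.image_shape[0] / 2, 0), extend="both"
    )
    centerline_dist = float(np.abs(traj.points[:, 0] - geom.base_point()[0]).mean())
    return {
        "length_um": float(L0),
        "rot90_rel_err": float(abs(L90 - L0) / L0),
        "rot30_rel_err": float(abs(L30 - L0) / L0),
        "centerline_mean_dist_px": centerline_dist,
    }
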