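"""Wall-edge fluorescence profiles and their parametric models.

Cell-wall components distribute along the tube with characteristic shapes:
pectin methylesterase peaks in the apical dome (Gaussian), crystalline
cellulose and callose rise from the tip toward the shank (four- and
three-parameter logistic).  Profiles are sampled along the tube-mask
boundary from the apex outward (0-30 µm), replacing manual freehand lines
with a reproducible edge polyline.  Group structure is handled two-stage:
per-tube nonlinear least squares, then group statistics (mean, SEM, Welch
tests) on the fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind
from skimage import measure

from .exceptions import FitError, ParameterError, ProfileError
from .models import canonicalize_logistic, gaussian_peak, logistic3, logistic4
from .segmentation import GrowthTrajectory, smooth_polyline

__all__ = [
    "EdgeProfile",
    "extract_edge_profile",
    "fit_logistic4",
    "fit_logistic3",
    "fit_apex_gaussian",
    "compare_groups",
]


@dataclass
class EdgeProfile:
    """Intensity vs distance from the tip along one wall edge."""

    x: np.ndarray  # um from the apex, ascending from 0
    I: np.ndarray  # a.u.
    tube_id: str = "tube"
    side: str = "merged"  # left | right | merged

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if len(self.x) != len(self.I) or len(self.x) < 4:
            raise ParameterError("edge profile needs >= 4 matched samples")
        if np.any(np.diff(self.x) <= 0):
            raise ParameterError("x must be strictly ascending")


def _snap_to_ridge(image_smooth, mask, arm, search_px):
    """Move each boundary vertex inward onto the local wall-intensity ridge.

    The segmentation boundary sits roughly a half-width outside the bright
    wall line; each vertex is shifted along its inward normal to the nearby
    intensity maximum so arc lengths are measured on the wall itself.
    """
    d = np.gradient(arm, axis=0)
    norms = np.hypot(d[:, 0], d[:, 1])
    norms[norms == 0] = 1.0
    normal = np.stack([-d[:, 1], d[:, 0]], axis=1) / norms[:, None]
    # orient normals into the mask
    probe = np.clip(np.rint(arm + 2.0 * normal).astype(int), 0, np.array(mask.shape) - 1)
    sign = np.where(mask[probe[:, 0], probe[:, 1]], 1.0, -1.0)
    normal *= sign[:, None]
    ts = np.linspace(0.0, search_px, max(int(search_px * 4), 8))
    cand = arm[:, None, :] + ts[None, :, None] * normal[:, None, :]
    vals = ndi.map_coordinates(
        image_smooth, [cand[..., 0].ravel(), cand[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(len(arm), len(ts))
    best = np.argmax(vals, axis=1)
    return arm + ts[best][:, None] * normal


def _sample_contour_arm(image, image_smooth, mask, arm, pixel_size, length_um, search_px):
    """Resample intensity along one wall arm onto a uniform x grid."""
    ridge = _snap_to_ridge(image_smooth, mask, arm, search_px)
    # suppress marching-squares staircase jitter, which inflates arc length
    ridge = smooth_polyline(ridge, sigma=1.0)
    steps = np.hypot(*np.diff(ridge, axis=0).T) * pixel_size
    arc = np.concatenate(([0.0], np.cumsum(steps)))
    stop = min(length_um, arc[-1])
    x = np.arange(0.0, stop + pixel_size / 2, pixel_size)
    r = np.interp(x, arc, ridge[:, 0])
    c = np.interp(x, arc, ridge[:, 1])
    I = ndi.map_coordinates(np.asarray(image, dtype=float), [r, c], order=1, mode="nearest")
    return x, I


def extract_edge_profile(
    image: np.ndarray,
    tube_mask: np.ndarray,
    trajectory: GrowthTrajectory,
    length_um: float = 30.0,
    side: str = "merged",
    tube_id: str = "tube",
    search_um: float = 2.0,
) -> EdgeProfile:
    """Wall intensity profile from the apex outward, sampled on the wall ridge.

    The tube-mask boundary (subpixel contour) is split at the point nearest
    the trajectory tip into two arms; each boundary vertex is snapped inward
    to the local wall-intensity maximum (searching up to ``search_um`` along
    the normal), then intensity is sampled bilinearly along the snapped arm
    at ``pixel_size`` spacing with arc length measured on the wall itself.
    ``side`` selects one arm ("left", "right", ordered by the transverse
    coordinate at the apex) or their mean ("merged").  Profiles shorter than
    ``length_um`` are truncated with a warning.
    """
    px = trajectory.pixel_size
    bool_mask = np.asarray(tube_mask).astype(bool)
    mask = bool_mask.astype(float)
    image_smooth = ndi.gaussian_filter(np.asarray(image, dtype=float), 1.0)
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ProfileError("tube mask has no boundary contour")
    contour = max(contours, key=len)
    tip_pt = trajectory.point_at(trajectory.length_um)
    d = np.hypot(contour[:, 0] - tip_pt[0], contour[:, 1] - tip_pt[1])
    apex_i = int(np.argmin(d))
    # walk both directions from the apex
    arm_a = contour[apex_i:]
    arm_b = contour[: apex_i + 1][::-1]
    if len(arm_a) < 2 or len(arm_b) < 2:
        closed = np.allclose(contour[0], contour[-1])
        if closed:
            rolled = np.roll(contour[:-1], -apex_i, axis=0)
            arm_a = np.vstack([rolled, rolled[:1]])
            arm_b = arm_a[::-1]
        else:
            raise ProfileError("apex lies at an open boundary end")
    search_px = search_um / px
    xa, Ia = _sample_contour_arm(image, image_smooth, bool_mask, arm_a, px, length_um, search_px)
    xb, Ib = _sample_contour_arm(image, image_smooth, bool_mask, arm_b, px, length_um, search_px)
    if min(xa[-1], xb[-1]) < length_um - px:
        warnings.warn(
            f"edge shorter than requested {length_um} um; truncated at "
            f"{min(xa[-1], xb[-1]):.1f} um"
        )
    # order arms left/right by the transverse position of their early samples
    tangent = trajectory.tangent_at(trajectory.length_um)
    normal = np.array([-tangent[1], tangent[0]])
    k = min(len(arm_a), len(arm_b), 10)
    wa = float(np.mean((arm_a[:k] - tip_pt) @ normal))
    wb = float(np.mean((arm_b[:k] - tip_pt) @ normal))
    arms = {"left": (xa, Ia), "right": (xb, Ib)} if wa <= wb else {"left": (xb, Ib), "right": (xa, Ia)}
    if side in ("left", "right"):
        x, I = arms[side]
    elif side == "merged":
        xl, Il = arms["left"]
        xr, Ir = arms["right"]
        n = min(len(xl), len(xr))
        x = xl[:n]
        I = 0.5 * (Il[:n] + Ir[:n])
    else:
        raise ParameterError(f"side must be left/right/merged; got {side!r}")
    return EdgeProfile(x=x, I=I, tube_id=tube_id, side=side)


# ---------------------------------------------------------------------------
# Per-tube model fits with two-stage group statistics
# ---------------------------------------------------------------------------


def _as_xy(profile):
    if isinstance(profile, EdgeProfile):
        return profile.x, profile.I, profile.tube_id
    x, I = profile
    return np.asarray(x, dtype=float), np.asarray(I, dtype=float), None


def _rmse(y, yhat):
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _fit_one_logistic4(x, y):
    a0, b0 = float(y.min()), float(y.max())
    if b0 - a0 <= 0:
        raise FitError("flat profile: logistic asymptotes unidentifiable")
    half = (a0 + b0) / 2.0
    crossings = np.flatnonzero(np.diff(np.sign(y - half)))
    x_mid0 = float(x[crossings[0]]) if len(crossings) else float(np.median(x))
    s0 = (x[-1] - x[0]) / 10.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                logistic4, x, y, p0=[a0, b0, x_mid0, s0], maxfev=5000
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    A, B, x_mid, s = canonicalize_logistic(*popt)
    if s <= 0 or not np.isfinite([A, B, x_mid, s]).all():
        raise FitError("degenerate 4PL fit")
    return {
        "lower": A,
        "upper": B,
        "x_mid": x_mid,
        "scale": s,
        "rmse": _rmse(y, logistic4(x, A, B, x_mid, s)),
    }


def _fit_one_logistic3(x, y):
    b0 = float(y.max())
    if b0 <= 0 or np.ptp(y) == 0:
        raise FitError("flat or non-positive profile: 3PL unidentifiable")
    half = b0 / 2.0
    crossings = np.flatnonzero(np.diff(np.sign(y - half)))
    x_mid0 = float(x[crossings[0]]) if len(crossings) else float(np.median(x))
    s0 = (x[-1] - x[0]) / 10.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(logistic3, x, y, p0=[b0, x_mid0, s0], maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"3PL fit did not converge: {exc}") from exc
    B, x_mid, s = popt
    if s < 0:  # sign degeneracy with A=0 fixed cannot swap asymptotes; reject
        raise FitError("3PL fit converged to a decreasing branch")
    return {
        "upper": float(B),
        "x_mid": float(x_mid),
        "scale": float(s),
        "rmse": _rmse(y, logistic3(x, B, x_mid, s)),
    }


def _fit_one_gaussian(x, y, window_um):
    sel = x <= window_um
    xs, ys = x[sel], y[sel]
    if len(xs) < 5:
        raise FitError("too few samples in the apical window")
    if np.ptp(ys) == 0:
        raise FitError("flat apical profile has no peak")
    b0 = float(ys.min())
    a0 = float(np.ptp(ys))
    mu0 = float(xs[np.argmax(ys)])
    s0 = max((xs[-1] - xs[0]) / 6.0, np.diff(xs).min())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                gaussian_peak,
                xs,
                ys,
                p0=[a0, mu0, s0, b0],
                bounds=([0, xs[0] - (xs[-1] - xs[0]), 1e-6, -np.inf],
                        [np.inf, xs[-1], 2 * (xs[-1] - xs[0]), np.inf]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"apex Gaussian fit did not converge: {exc}") from exc
    a, mu, sig, b = (float(v) for v in popt)
    if a <= 0 or sig <= 0:
        raise FitError("degenerate apex Gaussian fit")
    return {
        "amplitude": a,
        "center": mu,
        "width": sig,
        "baseline": b,
        "rmse": _rmse(ys, gaussian_peak(xs, a, mu, sig, b)),
    }


def _fit_cohort(profiles, fit_one, model_name, max_fail_frac=0.5, **kwargs):
    rows = []
    n_fail = 0
    for i, prof in enumerate(profiles):
        x, y, tube_id = _as_xy(prof)
        tube_id = tube_id or f"tube{i:03d}"
        try:
            params = fit_one(x, y, **kwargs)
        except FitError as exc:
            warnings.warn(f"{tube_id}: {model_name} fit failed ({exc})")
            n_fail += 1
            continue
        rows.append({"tube_id": tube_id, "model": model_name, **params})
    if not rows or n_fail / max(len(rows) + n_fail, 1) > max_fail_frac:
        raise FitError(
            f"{model_name}: {n_fail} of {n_fail + len(rows)} tubes failed to fit"
        )
    fits = pd.DataFrame(rows)
    param_cols = [c for c in fits.columns if c not in ("tube_id", "model")]
    summary = pd.DataFrame(
        {
            "mean": fits[param_cols].mean(),
            "sem": fits[param_cols].sem(),
            "n_tubes": len(fits),
        }
    )
    return fits, summary


def fit_logistic4(profiles):
    """Per-tube 4PL fits and a (mean, SEM) group summary.

    Two-stage emulation of a nonlinear mixed model with tube as the random
    factor: parameters are estimated per tube, then summarized across tubes.
    Returns (per-tube DataFrame, summary DataFrame).
    """
    return _fit_cohort(profiles, _fit_one_logistic4, "logistic4")


def fit_logistic3(profiles):
    """Per-tube 3PL fits (lower asymptote fixed at 0) and a group summary."""
    return _fit_cohort(profiles, _fit_one_logistic3, "logistic3")


def fit_apex_gaussian(profiles, window_um: float = 15.0):
    """Per-tube apical-dome Gaussian fits over the first ``window_um`` µm."""
    return _fit_cohort(profiles, _fit_one_gaussian, "gaussian", window_um=window_um)


def compare_groups(per_tube_params: pd.DataFrame, group_col: str = "group"):
    """Group means, SEMs, and Welch-test p-values per fitted parameter.

    With more than two groups, each group is tested against the first
    (control).  Requires >= 2 groups with >= 3 tubes each.
    """
    if group_col not in per_tube_params.columns:
        raise ParameterError(f"missing {group_col!r} column")
    groups = list(per_tube_params[group_col].unique())
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups to compare")
    counts = per_tube_params.groupby(group_col).size()
    if (counts < 3).any():
        raise ParameterError(f"each group needs >= 3 tubes; got {counts.to_dict()}")
    param_cols = [
        c
        for c in per_tube_params.columns
        if c not in (group_col, "tube_id", "model") and np.issubdtype(per_tube_params[c].dtype, np.number)
    ]
    control = groups[0]
    rows = []
    for param in param_cols:
        for g in groups:
            vals = per_tube_params.loc[per_tube_params[group_col] == g, param]
            if g == control:
                pval = np.nan
            else:
                ref = per_tube_params.loc[per_tube_params[group_col] == control, param]
                pval = float(ttest_ind(ref, vals, equal_var=False).pvalue)
            rows.append(
                {
                    "parameter": param,
                    "group": g,
                    "mean": float(vals.mean()),
                    "sem": float(vals.sem()),
                    "n_tubes": int(len(vals)),
                    "p_vs_control": pval,
                }
            )
    return pd.DataFrame(rows)
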