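"""Synthetic time-lapse, ROI, and profile generators with known ground truth.

The simulator emulates the statistical structure of pulsed pollen-tube tip
growth: a straight tube of ~8 µm diameter whose tip advances with a
sinusoidally pulsed velocity, an apical cell wall whose fluorescence
cross-section is Gaussian and whose thickness oscillates with a phase lead
over velocity, punctate apical staining covering a prescribed area fraction,
and wall-edge fluorescence gradients with Gaussian or logistic shape.

The sinusoidal waveform is a modelling choice: it makes the phase lead of
thickening over elongation analytically well defined, so every downstream
estimator can be checked against closed-form truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from . import models
from .exceptions import ParameterError
from .stack import TimeLapseStack

__all__ = [
    "KinematicsParams",
    "TubeGeometry",
    "GroundTruth",
    "generate_kinematics",
    "render_frame",
    "support_mask",
    "render_stack",
    "generate_profile_samples",
    "generate_roi_image",
    "render_wall_profile_image",
    "PROFILE_MODELS",
]


@dataclass(frozen=True)
class KinematicsParams:
    """Ground-truth kinematics of pulsed tip growth.

    velocity(t) = v0 + Av * sin(2*pi*t/T)
    sigma(t)    = w0 + Aw * sin(2*pi*(t + delta)/T)

    ``delta >= 0`` is the phase lead of wall thickness over velocity in
    seconds: thickening peaks ``delta`` seconds before the elongation peak,
    matching the observation that wall-material secretion precedes tip
    extension during oscillatory growth.
    """

    v0: float = 0.3  # baseline tip speed, um/s
    Av: float = 0.2  # velocity oscillation amplitude, um/s
    w0: float = 0.5  # baseline apical wall thickness (Gaussian sigma), um
    Aw: float = 0.15  # thickness oscillation amplitude, um
    T: float = 40.0  # oscillation period, s
    delta: float = 20.0  # phase lead of thickness over velocity, s
    duration: float = 240.0  # total simulated time, s
    dt: float = 1.0  # frame interval, s
    seed: int = 0

    def validate(self) -> None:
        if not (self.v0 >= self.Av >= 0):
            raise ParameterError(
                f"require v0 >= Av >= 0 (velocity never negative); got v0={self.v0}, Av={self.Av}"
            )
        if not (self.w0 > self.Aw >= 0):
            raise ParameterError(
                f"require w0 > Aw >= 0; got w0={self.w0}, Aw={self.Aw}"
            )
        if not (0 <= self.delta < self.T):
            raise ParameterError(f"require 0 <= delta < T; got delta={self.delta}, T={self.T}")
        if not (self.dt > 0):
            raise ParameterError(f"require dt > 0; got dt={self.dt}")
        if not (self.duration >= 3 * self.T):
            raise ParameterError(
                f"require duration >= 3*T; got duration={self.duration}, T={self.T}"
            )


@dataclass(frozen=True)
class TubeGeometry:
    """Optical and geometric parameters of the rendered tube.

    The tube is rendered straight, entering from the left image border along
    the row ``image_shape[0] // 2`` unless ``origin``/``angle_deg`` say
    otherwise.  Only the cell wall fluoresces: the image is two parallel wall
    lines of Gaussian transverse cross-section joined by a hemispherical cap,
    so the intensity along the centerline near the apex is a Gaussian of
    standard deviation ``sigma(t)`` centered on the tip position.
    """

    radius: float = 4.0  # tube radius, um
    base_length: float = 15.0  # tube length at t=0, um
    wall_peak_intensity: float = 100.0  # a.u.
    background: float = 5.0  # a.u.
    psf_sigma: float = 0.1  # optical blur (Gaussian sd), um
    pixel_size: float = 0.2  # um/px
    image_shape: tuple = (64, 560)  # (rows, cols)
    noise_gaussian_sd: float = 0.0  # a.u.
    noise_poisson: bool = False
    angle_deg: float = 0.0  # tube axis angle (0 = horizontal, growing right)
    origin: tuple | None = None  # (row, col) of tube base in px; default (rows//2, 0)

    def validate(self) -> None:
        if not (self.radius > 0):
            raise ParameterError(f"radius must be > 0; got {self.radius}")
        if not (self.pixel_size > 0):
            raise ParameterError(f"pixel_size must be > 0; got {self.pixel_size}")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ParameterError(f"image_shape must be a (rows, cols) pair; got {self.image_shape}")

    def base_point(self) -> np.ndarray:
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        return np.array([self.image_shape[0] / 2.0, 0.0])

    def axis_unit(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        # (row, col) components; angle 0 grows toward increasing columns
        return np.array([-math.sin(a), math.cos(a)])


@dataclass
class GroundTruth:
    """True kinematic series underlying a rendered stack."""

    time: np.ndarray  # s
    tip_um: np.ndarray  # tip position along the axis, um
    sigma_um: np.ndarray  # apical wall thickness (Gaussian sd), um
    velocity: np.ndarray  # um/s
    T: float
    delta: float

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.tip_um) == len(self.sigma_um) == len(self.velocity) == n):
            raise ParameterError("ground-truth series must have equal lengths")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.time,
                "tip_um": self.tip_um,
                "sigma_um": self.sigma_um,
                "velocity_um_s": self.velocity,
            }
        )


def generate_kinematics(p: KinematicsParams, base_length_um: float = 0.0) -> GroundTruth:
    """Deterministic pulsed-growth kinematic series (no noise at this stage).

    Tip position is the cumulative trapezoidal integral of velocity starting
    at ``base_length_um``.
    """
    p.validate()
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    omega = 2 * np.pi / p.T
    velocity = p.v0 + p.Av * np.sin(omega * t)
    sigma = p.w0 + p.Aw * np.sin(omega * (t + p.delta))
    tip = base_length_um + np.concatenate(([0.0], cumulative_trapezoid(velocity, t)))
    return GroundTruth(time=t, tip_um=tip, sigma_um=sigma, velocity=velocity, T=p.T, delta=p.delta)


def _tube_coords(geom: TubeGeometry):
    """Axial/transverse coordinate grids (um) of every pixel in the tube frame."""
    rows, cols = geom.image_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    p0 = geom.base_point()
    ax = geom.axis_unit()
    dr = (rr - p0[0]) * geom.pixel_size
    dc = (cc - p0[1]) * geom.pixel_size
    u = dr * ax[0] + dc * ax[1]
    w = -dr * ax[1] + dc * ax[0]
    return u, w


def _outline_distance(u, w, tip_um, radius):
    """Unsigned distance (um) from each pixel to the tube outline.

    The outline is a stadium: two lines at |w| = radius for u <= tip - radius,
    closed by a semicircular cap of the same radius centered at
    (u, w) = (tip - radius, 0).
    """
    cap_u = tip_um - radius
    in_shank = u <= cap_u
    d_shank = np.abs(np.abs(w) - radius)
    d_cap = np.abs(np.hypot(u - cap_u, w) - radius)
    return np.where(in_shank, d_shank, d_cap)


def _inside(u, w, tip_um, radius):
    cap_u = tip_um - radius
    shank = (u >= 0) & (u <= cap_u) & (np.abs(w) <= radius)
    # behind the base the tube continues out of the field of view
    behind = (u < 0) & (np.abs(w) <= radius)
    cap = (u > cap_u) & (np.hypot(u - cap_u, w) <= radius)
    return shank | behind | cap


def render_frame(tip_um: float, sigma_um: float, geom: TubeGeometry) -> np.ndarray:
    """Noiseless, blur-free wall-fluorescence image for one time point."""
    u, w = _tube_coords(geom)
    dist = _outline_distance(u, w, tip_um, geom.radius)
    img = geom.background + geom.wall_peak_intensity * np.exp(
        -(dist**2) / (2.0 * sigma_um**2)
    )
    return img


def support_mask(tip_um: float, sigma_um: float, geom: TubeGeometry, level: float = 0.5) -> np.ndarray:
    """Ground-truth filled tube support out to the given wall-intensity level.

    The mask contains the tube interior plus the outer wall shell where the
    (unblurred) wall Gaussian still exceeds ``level`` of its peak.
    """
    u, w = _tube_coords(geom)
    dist = _outline_distance(u, w, tip_um, geom.radius)
    margin = sigma_um * math.sqrt(2.0 * math.log(1.0 / level))
    return _inside(u, w, tip_um, geom.radius) | (dist <= margin)


def true_centerline(geom: TubeGeometry, tip_um: float, step_px: float = 1.0) -> np.ndarray:
    """Ground-truth centerline polyline in pixel coordinates, base to apex."""
    n = int(math.floor(tip_um / geom.pixel_size / step_px)) + 1
    s = np.arange(n) * step_px  # px along axis
    p0 = geom.base_point()
    ax = geom.axis_unit()
    return p0[None, :] + s[:, None] * ax[None, :]


def render_stack(g: GroundTruth, geom: TubeGeometry, seed: int | None = 0) -> TimeLapseStack:
    """Render the full time lapse: geometry, optical blur, then noise.

    Identical ``seed`` and parameters give bit-identical stacks.  Raises if
    the tip (plus a half-max wall margin) leaves the field of view, naming
    the offending frame.
    """
    geom.validate()
    rng = np.random.default_rng(seed)
    rows, cols = geom.image_shape
    u, w = _tube_coords(geom)
    p0 = geom.base_point()
    ax = geom.axis_unit()
    frames = np.empty((g.n_frames, rows, cols), dtype=float)
    blur_px = geom.psf_sigma / geom.pixel_size
    for i in range(g.n_frames):
        tip = g.tip_um[i]
        sig = g.sigma_um[i]
        apex = p0 + ax * (tip + 2.0 * sig) / geom.pixel_size
        if not (0 <= apex[0] <= rows - 1 and 0 <= apex[1] <= cols - 1):
            raise ParameterError(
                f"tip exits the field of view at frame {i} (apex at px {apex})"
            )
        dist = _outline_distance(u, w, tip, geom.radius)
        img = geom.background + geom.wall_peak_intensity * np.exp(-(dist**2) / (2.0 * sig**2))
        if blur_px > 0:
            img = gaussian_filter(img, blur_px)
        if geom.noise_poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if geom.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, geom.noise_gaussian_sd, size=img.shape)
        frames[i] = np.clip(img, 0.0, None)
    dt = float(g.time[1] - g.time[0])
    return TimeLapseStack(
        frames=frames,
        pixel_size=geom.pixel_size,
        dt=dt,
        metadata={"seed": seed, "radius_um": geom.radius},
    )


# ---------------------------------------------------------------------------
# 1-D wall-deposition profile samples
# ---------------------------------------------------------------------------

PROFILE_MODELS = {
    "gaussian": (models.gaussian_peak, ("amplitude", "center", "sigma", "baseline")),
    "logistic3": (models.logistic3, ("upper", "x_mid", "scale")),
    "logistic4": (models.logistic4, ("lower", "upper", "x_mid", "scale")),
}


def generate_profile_samples(
    kind: str,
    params: dict,
    x_grid: np.ndarray,
    noise_sd: float,
    n_tubes: int,
    seed: int | None = 0,
    jitter: dict | None = None,
):
    """Per-tube fluorescence-vs-distance profiles with known parameters.

    Each tube's parameters are the population values in ``params`` plus
    independent Gaussian between-tube jitter (``jitter`` maps parameter name
    to its sd); residual noise is i.i.d. Gaussian(0, noise_sd) per sample.

    Returns
    -------
    profiles : ndarray, shape (n_tubes, len(x_grid))
    truths : DataFrame with one row of true parameters per tube
    """
    if kind not in PROFILE_MODELS:
        raise ParameterError(f"unknown profile kind {kind!r}; choose from {sorted(PROFILE_MODELS)}")
    x = np.asarray(x_grid, dtype=float)
    if x.ndim != 1 or len(x) < 3 or np.any(np.diff(x) <= 0):
        raise ParameterError("x_grid must be 1-D and strictly ascending")
    if np.any(x < 0):
        raise ParameterError("x_grid must be non-negative (distance from tip)")
    func, names = PROFILE_MODELS[kind]
    missing = set(names) - set(params)
    if missing:
        raise ParameterError(f"missing parameters for {kind}: {sorted(missing)}")
    jitter = jitter or {}
    rng = np.random.default_rng(seed)
    truths = {name: np.full(n_tubes, float(params[name])) for name in names}
    for name, sd in jitter.items():
        if name not in truths:
            raise ParameterError(f"jitter refers to unknown parameter {name!r}")
        truths[name] = truths[name] + rng.normal(0.0, sd, size=n_tubes)
    profiles = np.empty((n_tubes, len(x)))
    for i in range(n_tubes):
        args = [truths[name][i] for name in names]
        profiles[i] = func(x, *args)
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)
    return profiles, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# ROI puncta images
# ---------------------------------------------------------------------------


def generate_roi_image(
    roi_shape: tuple,
    target_fraction: float,
    puncta_radius: int,
    seed: int | None = 0,
    background: float = 10.0,
    puncta_intensity: float = 100.0,
    noise_sd: float = 0.0,
    tolerance_pp: float = 0.5,
    max_attempts: int = 200_000,
):
    """Punctate-staining image whose covered-area fraction is known exactly.

    Bright disks are dropped at random, rejecting overlaps while the target
    remains reachable that way; random sequential placement of hard disks
    jams a little above 50% coverage, so for dense targets placement falls
    back to permitting overlap.  The returned fraction is computed from the
    realized union mask, so the ground truth is exact either way.

    Returns (image, realized_fraction_pct, placement_mask).
    """
    if not (0 <= target_fraction <= 100):
        raise ParameterError(f"target_fraction must be in [0, 100]; got {target_fraction}")
    rows, cols = roi_shape
    mask = np.zeros((rows, cols), dtype=bool)
    rng = np.random.default_rng(seed)

    if target_fraction == 100:
        mask[:] = True
    elif target_fraction > 0:
        r = int(puncta_radius)
        if r < 1 or 2 * r + 1 > min(rows, cols):
            raise ParameterError(f"puncta_radius {puncta_radius} unusable for ROI {roi_shape}")
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (yy**2 + xx**2) <= r**2
        area = mask.size
        disk_pp = 100.0 * disk.sum() / area
        if disk_pp > 2 * tolerance_pp and target_fraction < disk_pp - tolerance_pp:
            raise ParameterError(
                f"target {target_fraction}% unreachable: one disk already covers {disk_pp:.2f}%"
            )
        consecutive_rejects = 0
        allow_overlap = False
        attempts = 0
        while 100.0 * mask.sum() / area < target_fraction - tolerance_pp:
            attempts += 1
            if attempts > max_attempts:
                raise ParameterError(
                    f"target {target_fraction}% unreachable with radius {puncta_radius} "
                    f"after {max_attempts} attempts"
                )
            cr = rng.integers(r, rows - r)
            cc = rng.integers(r, cols - r)
            patch = mask[cr - r : cr + r + 1, cc - r : cc + r + 1]
            overlap = np.any(patch & disk)
            if overlap and not allow_overlap:
                consecutive_rejects += 1
                if consecutive_rejects > 2000:
                    allow_overlap = True
                continue
            gain = np.count_nonzero(disk & ~patch)
            if gain == 0:
                continue
            frac_next = 100.0 * (mask.sum() + gain) / area
            if frac_next > target_fraction + tolerance_pp:
                continue  # this placement would overshoot; try another spot
            patch |= disk
            consecutive_rejects = 0

    realized = 100.0 * mask.sum() / mask.size
    image = np.full((rows, cols), background, dtype=float)
    image[mask] = puncta_intensity
    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, size=image.shape), 0.0, None)
    return image, realized, mask


# ---------------------------------------------------------------------------
# Single-frame images whose wall intensity follows a known distance profile
# ---------------------------------------------------------------------------


def wall_arc_distance(u, w, tip_um, radius):
    """Distance from the apex along the tube outline (um), per pixel.

    On the cap the distance is the arc ``radius * angle`` from the apex; past
    the cap it continues linearly down the straight wall.  Used to paint a
    known fluorescence-vs-distance-from-tip gradient onto the wall.
    """
    cap_u = tip_um - radius
    du = u - cap_u
    angle = np.arctan2(np.abs(w), du)  # 0 at the apex direction, pi/2 at the flank
    arc = radius * angle
    shank_extra = np.clip(cap_u - u, 0.0, None)
    return np.where(u > cap_u, arc, radius * (np.pi / 2) + shank_extra)


def render_wall_profile_image(
    geom: TubeGeometry,
    tip_um: float,
    sigma_um: float,
    profile_fn,
    seed: int | None = None,
):
    """Render one frame whose wall peak intensity varies with distance from tip.

    ``profile_fn(x_um)`` gives the wall intensity at outline distance ``x``
    from the apex.  Returns (image, geometry ground truth is implicit in the
    arguments).
    """
    geom.validate()
    u, w = _tube_coords(geom)
    dist = _outline_distance(u, w, tip_um, geom.radius)
    x = wall_arc_distance(u, w, tip_um, geom.radius)
    img = geom.background + profile_fn(x) * np.exp(-(dist**2) / (2.0 * sigma_um**2))
    blur_px = geom.psf_sigma / geom.pixel_size
    if blur_px > 0:
        img = gaussian_filter(img, blur_px)
    if seed is not None and geom.noise_gaussian_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, geom.noise_gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)
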