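"""ROI-based quantification of apical structures.

Emulates the four-step quantification pipeline used for actin-fringe and
vesicle-marker images: align the tube vertically, build a 5 µm tip ROI and a
60 µm shank/distal ROI along the growth trajectory, segment the staining
inside each ROI, and tabulate percent covered area and mean intensity.
Distance from the tip is measured along the trajectory arc length (each
pixel projects to its nearest trajectory point), which is robust to tube
curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .exceptions import ParameterError, RoiError
from .segmentation import GrowthTrajectory

__all__ = [
    "RoiSpec",
    "align_vertical",
    "roi_from_tip",
    "build_rois",
    "segment_staining",
    "tabulate",
    "tip_shank_ratio",
]


@dataclass(frozen=True)
class RoiSpec:
    """Tip/shank ROI extents along the trajectory (µm from the tip)."""

    tip_length: float = 5.0
    shank_length: float = 60.0

    def validate(self):
        if self.tip_length <= 0 or self.shank_length <= 0:
            raise ParameterError("ROI lengths must be > 0")


def _terminal_tangent(trajectory: GrowthTrajectory, window_um=20.0, exclude_um=7.0):
    """Unit base->tip tangent from a total-least-squares line fit near the tip.

    The fit window excludes the last few micrometres, where the discrete
    medial axis bends into the apical cap.
    """
    L = trajectory.length_um
    sel = (trajectory.arclength >= L - window_um) & (trajectory.arclength <= L - exclude_um)
    pts = trajectory.points[sel]
    if len(pts) < 5:
        return trajectory.tangent_at(L, window_points=10)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return d


def align_vertical(image: np.ndarray, trajectory: GrowthTrajectory, order: int = 1):
    """Rotate the image so the tube's terminal tangent points up (tip at top).

    The rotation is rigid, about the image center, with the output canvas
    enlarged to hold the rotated content; the trajectory is transformed with
    the same map.  Returns (rotated image, rotated trajectory, angle_deg).
    """
    image = np.asarray(image, dtype=float)
    tangent = _terminal_tangent(trajectory)  # unit (row, col), base->tip
    alpha = math.atan2(tangent[0], tangent[1])
    beta = -math.pi / 2 - alpha  # rotate tangent onto "up" = (-1, 0)
    # normalize to (-pi, pi] so the reported angle is minimal
    beta = (beta + math.pi) % (2 * math.pi) - math.pi
    cb, sb = math.cos(beta), math.sin(beta)
    # adds beta to atan2(row, col) of a (row, col) vector
    M = np.array([[cb, sb], [-sb, cb]])
    rows, cols = image.shape
    c_in = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    corners = np.array([[0, 0], [0, cols - 1], [rows - 1, 0], [rows - 1, cols - 1]], dtype=float)
    q = (corners - c_in) @ M.T
    qmin, qmax = q.min(axis=0), q.max(axis=0)
    out_shape = tuple(int(math.ceil(v)) + 1 for v in (qmax - qmin))
    Minv = M.T  # rotation inverse
    offset = Minv @ qmin + c_in
    rotated = ndi.affine_transform(
        image, Minv, offset=offset, output_shape=out_shape, order=order, mode="constant", cval=0.0
    )
    forward = lambda p: M @ (np.asarray(p, dtype=float) - c_in) - qmin
    traj_rot = trajectory.transformed(forward)
    return rotated, traj_rot, math.degrees(beta)


def _distance_from_tip(tube_mask: np.ndarray, trajectory: GrowthTrajectory) -> np.ndarray:
    """Per-pixel distance from the tip (µm) along the trajectory arc length."""
    pix = np.argwhere(tube_mask)
    if len(pix) == 0:
        raise RoiError("empty tube mask")
    tree = cKDTree(trajectory.points)
    _, idx = tree.query(pix.astype(float))
    s_from_tip = trajectory.length_um - trajectory.arclength[idx]
    dist = np.full(tube_mask.shape, np.inf)
    dist[pix[:, 0], pix[:, 1]] = s_from_tip
    return dist


def roi_from_tip(
    tube_mask: np.ndarray,
    trajectory: GrowthTrajectory,
    s_min_um: float,
    s_max_um: float,
) -> np.ndarray:
    """Tube-mask pixels whose distance from the tip is in (s_min, s_max]."""
    dist = _distance_from_tip(tube_mask, trajectory)
    roi = (dist > s_min_um) & (dist <= s_max_um) if s_min_um > 0 else (dist <= s_max_um)
    return roi & np.asarray(tube_mask, dtype=bool)


def build_rois(
    tube_mask: np.ndarray,
    trajectory: GrowthTrajectory,
    spec: RoiSpec | None = None,
):
    """Disjoint (tip ROI, shank ROI) masks within the tube mask.

    Tip ROI: distance from tip <= tip_length; shank ROI: distance in
    (tip_length, tip_length + shank_length].  Raises :class:`RoiError` when
    the tube is too short to hold a nonempty shank ROI.
    """
    spec = spec or RoiSpec()
    spec.validate()
    dist = _distance_from_tip(tube_mask, trajectory)
    mask = np.asarray(tube_mask, dtype=bool)
    tip = (dist <= spec.tip_length) & mask
    shank = (dist > spec.tip_length) & (dist <= spec.tip_length + spec.shank_length) & mask
    if not tip.any():
        raise RoiError("tip ROI is empty")
    if not shank.any():
        raise RoiError(
            f"tube too short: no pixels beyond {spec.tip_length} um from the tip"
        )
    return tip, shank


def segment_staining(
    image: np.ndarray,
    roi_mask: np.ndarray,
    method: str = "otsu",
    k: float = 3.0,
    min_size: int = 4,
) -> np.ndarray:
    """Segment stained structures within an ROI; returns a mask subset of it.

    ``method="otsu"`` thresholds the ROI histogram with Otsu's criterion and
    keeps the result only if the threshold clears the background by a robust
    contrast margin (k * MAD of the sub-threshold pixels), so noise-only and
    constant ROIs yield an empty mask.  ``method="mad"`` uses the classic
    median + k*MAD background threshold (reliable only below ~50% coverage).
    Objects smaller than ``min_size`` pixels are removed.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise RoiError("empty ROI")
    vals = np.asarray(image, dtype=float)[roi_mask]
    out = np.zeros_like(roi_mask)
    if np.ptp(vals) == 0:
        return out  # constant ROI: nothing stained
    if method == "otsu":
        thr = threshold_otsu(vals)
        below = vals[vals <= thr]
        if below.size == 0:
            return out
        mad = np.median(np.abs(below - np.median(below)))
        guard = k * 1.4826 * mad
        if thr - np.median(below) <= guard:
            return out  # no structure above the background noise
    elif method == "mad":
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        thr = med + k * 1.4826 * mad
    else:
        raise ParameterError(f"unknown staining method {method!r}")
    structure = (np.asarray(image, dtype=float) > thr) & roi_mask
    if min_size > 1 and structure.any():
        labels, n = ndi.label(structure)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        structure = np.isin(labels, keep)
    return structure


def tabulate(
    image: np.ndarray,
    rois: dict,
    structure_masks: dict | None = None,
    tube_id: str = "tube",
    staining_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One row per (tube, region): mean intensity and percent covered area.

    ``rois`` maps region name ("tip", "shank", ...) to its mask; structure
    masks are segmented with :func:`segment_staining` when not supplied.
    """
    image = np.asarray(image, dtype=float)
    rows = []
    for region, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise RoiError(f"ROI {region!r} is empty")
        if structure_masks is not None and region in structure_masks:
            struct = np.asarray(structure_masks[region], dtype=bool) & roi
        else:
            struct = segment_staining(image, roi, **(staining_kwargs or {}))
        rows.append(
            {
                "tube_id": tube_id,
                "region": region,
                "mean_intensity": float(image[roi].mean()),
                "area_fraction_pct": 100.0 * struct.sum() / roi.sum(),
            }
        )
    return pd.DataFrame(rows)


def tip_shank_ratio(results: pd.DataFrame) -> pd.Series:
    """Per-tube ratio of tip to shank mean fluorescence intensity."""
    ratios = {}
    for tube_id, grp in results.groupby("tube_id"):
        by_region = grp.set_index("region")["mean_intensity"]
        if "tip" not in by_region or "shank" not in by_region:
            raise RoiError(f"tube {tube_id}: both tip and shank must be measured")
        shank = by_region["shank"]
        if shank == 0:
            raise RoiError(f"tube {tube_id}: shank mean intensity is zero")
        ratios[tube_id] = by_region["tip"] / shank
    return pd.Series(ratios, name="tip_shank_ratio")
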