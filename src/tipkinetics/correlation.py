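"""Velocity autocorrelation and thickness-velocity cross-correlation.

Correlations are computed per tube on detrended series, averaged pointwise
across tubes, and the peak lag is located on the averaged curve with 3-point
parabolic refinement.  The biased (full-denominator) normalization keeps
values in [-1, 1] and is the standard choice for oscillation-lag detection.

Sign convention: a cross-correlation peak at positive lag k means thickness
changes precede velocity changes by k seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CorrelationError, PeakError

__all__ = [
    "CorrelationCurve",
    "PeakEstimate",
    "autocorrelation",
    "cross_correlation",
    "average_curves",
    "find_peak",
    "cohort_peak",
]


@dataclass
class CorrelationCurve:
    """Lag-indexed normalized correlation values on a symmetric lag grid."""

    lags: np.ndarray  # s, symmetric about 0, step dt
    values: np.ndarray  # dimensionless, |v| <= 1 (+ tiny numerical slack)
    n_tubes: int = 1

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise CorrelationError("lags and values must have equal length")


@dataclass(frozen=True)
class PeakEstimate:
    """Located correlation peak with between-tube uncertainty."""

    lag_s: float
    uncertainty_s: float  # SEM of per-tube refined peak lags
    n_tubes: int


def _lag_grid(n: int, dt: float, max_lag: float):
    k_max = min(n - 1, int(np.floor(max_lag / dt)))
    if k_max < 1:
        raise CorrelationError("max_lag shorter than one sample interval")
    return k_max


def autocorrelation(series, dt: float, max_lag: float) -> CorrelationCurve:
    """Biased autocorrelation rho(k) = sum_t x_t x_{t+k} / sum_t x_t^2."""
    x = np.asarray(series, dtype=float)
    denom = float(np.dot(x, x))
    if denom == 0:
        raise CorrelationError("zero-variance series has no autocorrelation")
    n = len(x)
    k_max = _lag_grid(n, dt, max_lag)
    full = np.correlate(x, x, mode="full")  # index n-1+k holds lag k
    center = n - 1
    values = full[center - k_max : center + k_max + 1] / denom
    lags = np.arange(-k_max, k_max + 1) * dt
    return CorrelationCurve(lags=lags, values=values)


def cross_correlation(thickness, velocity, dt: float, max_lag: float) -> CorrelationCurve:
    """Biased cross-correlation rho_wv(k) = sum_t w_t v_{t+k} / sqrt(sum w^2 sum v^2).

    A peak at positive lag means the thickness series leads the velocity
    series (thickening precedes elongation).
    """
    w = np.asarray(thickness, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if len(w) != len(v):
        raise CorrelationError("series must have equal length")
    denom = float(np.sqrt(np.dot(w, w) * np.dot(v, v)))
    if denom == 0:
        raise CorrelationError("zero-variance series has no cross-correlation")
    n = len(w)
    k_max = _lag_grid(n, dt, max_lag)
    # np.correlate(v, w, 'full')[n-1+k] = sum_j v_j w_{j-k} = sum_t w_t v_{t+k}
    full = np.correlate(v, w, mode="full")
    center = n - 1
    values = full[center - k_max : center + k_max + 1] / denom
    lags = np.arange(-k_max, k_max + 1) * dt
    return CorrelationCurve(lags=lags, values=values)


def average_curves(curves) -> CorrelationCurve:
    """Pointwise unweighted mean of per-tube curves on identical lag grids."""
    curves = list(curves)
    if not curves:
        raise CorrelationError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise CorrelationError("mismatched lag grids")
    values = np.mean([c.values for c in curves], axis=0)
    return CorrelationCurve(lags=lags, values=values, n_tubes=sum(c.n_tubes for c in curves))


def _refine_parabolic(lags: np.ndarray, values: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i-1, i, i+1 (grid lag if flat)."""
    if i == 0 or i == len(lags) - 1:
        return float(lags[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(lags[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(lags[i] + delta * (lags[i + 1] - lags[i]))


def find_peak(
    curve: CorrelationCurve,
    search_range: tuple | None = None,
    per_tube_curves=None,
) -> PeakEstimate:
    """First/highest local maximum in the searched lag range, refined.

    ``search_range`` defaults to positive lags only (excluding 0), which is
    the relevant window for a thickness-leads-velocity peak.  The discrete
    argmax within range must be a local maximum of the curve; it is refined
    by 3-point parabolic interpolation.  If ``per_tube_curves`` is given,
    the uncertainty is the SEM of per-tube refined peak lags.
    """
    lags, values = curve.lags, curve.values
    dt = float(lags[1] - lags[0])
    if search_range is None:
        search_range = (dt / 2.0, lags[-1])
    sel = (lags >= search_range[0]) & (lags <= search_range[1])
    if not sel.any():
        raise PeakError(f"search range {search_range} contains no lags")
    idx_candidates = np.flatnonzero(sel)
    # local maxima of the full curve restricted to the range
    local = []
    for i in idx_candidates:
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < len(values) - 1 else -np.inf
        if values[i] >= left and values[i] >= right:
            local.append(i)
    if not local:
        raise PeakError("no local maximum in the searched lag range")
    i_best = max(local, key=lambda i: values[i])
    lag = _refine_parabolic(lags, values, i_best)

    if per_tube_curves:
        per_lags = []
        for c in per_tube_curves:
            try:
                per_lags.append(find_peak(c, search_range=search_range).lag_s)
            except PeakError:
                continue
        if per_lags:
            per_lags = np.asarray(per_lags)
            sem = float(per_lags.std(ddof=1) / np.sqrt(len(per_lags))) if len(per_lags) > 1 else 0.0
            return PeakEstimate(lag_s=lag, uncertainty_s=sem, n_tubes=len(per_lags))
    return PeakEstimate(lag_s=lag, uncertainty_s=0.0, n_tubes=curve.n_tubes)


def cohort_peak(per_tube_curves, search_range: tuple | None = None):
    """Average a cohort of curves and locate the peak with SEM uncertainty.

    Returns (averaged curve, PeakEstimate).
    """
    avg = average_curves(per_tube_curves)
    peak = find_peak(avg, search_range=search_range, per_tube_curves=per_tube_curves)
    return avg, peak
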