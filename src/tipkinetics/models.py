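"""Parametric curve models shared by the simulator and the fitting stages.

All models use distance in micrometres and intensity in arbitrary units.
The logistic parameterization follows the standard dose-response form

    I(x) = A + (B - A) / (1 + exp((x_mid - x) / s))

with lower asymptote ``A``, upper asymptote ``B``, inflection ``x_mid`` and
scale ``s``.  The pair ``(A, B, s)`` and ``(B, A, -s)`` describe the same
curve; fits are canonicalized to ``s > 0``.
"""

from __future__ import annotations

import numpy as np


def gaussian_peak(x, amplitude, center, sigma, baseline):
    """Gaussian bump on a constant baseline."""
    x = np.asarray(x, dtype=float)
    return baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def logistic4(x, lower, upper, x_mid, scale):
    """Four-parameter logistic (sigmoid rising from ``lower`` to ``upper``)."""
    x = np.asarray(x, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((x_mid - x) / scale))


def logistic3(x, upper, x_mid, scale):
    """Three-parameter logistic: lower asymptote fixed at zero."""
    return logistic4(x, 0.0, upper, x_mid, scale)


def canonicalize_logistic(lower, upper, x_mid, scale):
    """Return the representative of the logistic sign-degeneracy with scale > 0."""
    if scale < 0:
        lower, upper, scale = upper, lower, -scale
    return lower, upper, x_mid, scale
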