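"""Shared angle conventions.

All angles handled by this package live on the 180°-periodic axis of a
transition dipole (dyad symmetry: a dipole at θ and θ+180° is the same
physical object).  Counter-clockwise is defined in the conventional display
orientation (y up), while image arrays index rows downward; every conversion
between a pixel displacement and an angle goes through :func:`axis_angle_deg`
so the handedness cannot silently flip between modules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "axis_angle_deg",
    "fold180",
    "circ_dist180",
    "weighted_circmean180",
    "weighted_circstd180",
]


def fold180(angle_deg):
    """Fold angles (degrees) onto the dipole axis range [0, 180)."""
    return np.mod(angle_deg, 180.0)


def axis_angle_deg(dx, dy_row):
    """Axis angle in degrees, CCW from +x in display (y-up) convention.

    Parameters
    ----------
    dx : array_like
        Displacement along columns (+x to the right).
    dy_row : array_like
        Displacement along rows (+ downward in the array).  The sign is
        flipped internally so the returned angle is counter-clockwise when
        the image is displayed with the origin at the top-left.
    """
    return fold180(np.degrees(np.arctan2(-np.asarray(dy_row, dtype=float),
                                         np.asarray(dx, dtype=float))))


def circ_dist180(a_deg, b_deg):
    """Shortest distance between two axis angles, result in [0, 90]."""
    d = np.abs(fold180(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)))
    return np.minimum(d, 180.0 - d)


def _resultant(angles_deg, weights):
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(1j * a))
    return z, np.sum(w)


def weighted_circmean180(angles_deg, weights=None):
    """Intensity-weighted circular mean of axis angles, in [0, 180)."""
    z, _ = _resultant(angles_deg, weights)
    if np.abs(z) == 0:
        raise ValueError("circular mean undefined: zero resultant")
    return fold180(np.degrees(np.angle(z)) / 2.0)


def weighted_circstd180(angles_deg, weights=None):
    """Circular standard deviation (degrees) of 180°-periodic axis data.

    Uses the wrapped-normal relation sd = sqrt(-2 ln R) on the doubled
    angles, halved back to the axis scale.
    """
    z, wsum = _resultant(angles_deg, weights)
    r = np.abs(z) / wsum
    if r <= 0:
        return np.inf
    r = min(float(r), 1.0)
    if r == 1.0:
        return 0.0
    return np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0
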