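"""Visual-field coordinate conventions.

The package works in visual-field degrees with x rightward, y upward and the
origin at fixation.  Polar angle is measured counterclockwise from the
*upper vertical meridian* in [0, 360): 0 deg is straight up, 90 deg is the
left horizontal meridian, 180 deg is straight down, 270 deg is the right
horizontal meridian.  Under this convention the left visual hemifield is the
open angle range (0, 180) and the right hemifield is (180, 360).
"""

from __future__ import annotations

import numpy as np

SECTOR_NAMES = ("upper", "middle_upper", "middle_lower", "lower")


def polar_angle(x, y):
    """Polar angle in degrees, CCW from the upper vertical meridian, [0, 360)."""
    ang = np.degrees(np.arctan2(y, x)) - 90.0
    return np.mod(ang, 360.0)


def eccentricity(x, y):
    return np.hypot(x, y)


def from_polar(angle_deg, ecc):
    """Inverse of (polar_angle, eccentricity): returns (x, y)."""
    a = np.radians(angle_deg)
    return -ecc * np.sin(a), ecc * np.cos(a)


def sector_index(angle_deg, hemifield):
    """Map polar angles to quadrant sectors of one hemifield.

    Sectors are four contiguous 45-degree wedges per hemifield, ordered from
    the upper vertical meridian toward the lower vertical meridian:
    ``upper, middle_upper, middle_lower, lower`` (indices 0..3).  Angles in
    the opposite hemifield map to -1.

    For the left hemifield the sectors are (0, 45], (45, 90], (90, 135],
    (135, 180); for the right hemifield [315, 360), [270, 315), [225, 270),
    (180, 225].  Points exactly on the vertical meridians (0 or 180) belong
    to no hemifield and map to -1.
    """
    a = np.asarray(angle_deg, dtype=float) % 360.0
    out = np.full(a.shape, -1, dtype=int)
    if hemifield == "left":
        inside = (a > 0) & (a < 180)
        out[inside] = np.minimum((a[inside] / 45.0).astype(int), 3)
    elif hemifield == "right":
        inside = (a > 180) & (a < 360)
        out[inside] = np.minimum(((360.0 - a[inside]) / 45.0).astype(int), 3)
    else:
        raise ValueError(f"hemifield must be 'left' or 'right', got {hemifield!r}")
    return out


def field_grid(max_ecc, n_samples):
    """Square field grid with samples at pixel centres over +-max_ecc.

    Returns (xs, ys, X, Y) where xs/ys are 1-D axes and X/Y the meshgrid.
    Row index increases with y (y upward in visual space).
    """
    step = 2.0 * max_ecc / n_samples
    xs = (np.arange(n_samples) + 0.5) * step - max_ecc
    ys = (np.arange(n_samples) + 0.5) * step - max_ecc
    X, Y = np.meshgrid(xs, ys)
    return xs, ys, X, Y
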