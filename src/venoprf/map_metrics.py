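"""Visual-field coverage and map-smoothness metrics.

Coverage: the fitted pRFs of an ROI are rendered as a normalised density
over the visual field (by default the envelope — pointwise maximum — of
unit-height Gaussian pRF profiles), binarised at a density threshold
(default 0.8), and the
percentage of each 45-degree hemifield sector covered is computed on the
field grid.  A sector counts as "complete" when its percentage, rounded
half-up to a whole number, reaches the cutoff (default 20 %).

Smoothness: the ROI's polar-angle map is rendered as a grayscale image
oriented so the principal angle gradient runs along the image x-axis; the
per-column mean luminance, min-max normalised across columns, is summarised
by its total variation.  An ideal map — a monotone ramp spanning the full
range — scores 1; disturbances (e.g. uncorrected inverted voxels mapping
non-neighbouring field positions) raise the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import SECTOR_NAMES, field_grid, sector_index


@dataclass(frozen=True)
class QuadrantSpec:
    """One hemifield split into four 45-degree sectors, upper to lower."""

    hemifield: str = "left"
    sectors: tuple = SECTOR_NAMES

    def sector_of(self, angle_deg):
        return sector_index(angle_deg, self.hemifield)


@dataclass
class CoverageReport:
    percent: dict          # sector -> [0, 100]
    complete: dict         # sector -> bool
    density_threshold: float
    cutoff_percent: float
    roi_name: str = ""


@dataclass
class SmoothnessResult:
    column_profile: np.ndarray
    smoothness: float
    degenerate: bool = False


def prf_density(x0, y0, sigma, usable=None, max_ecc: float = 5.5,
                grid_samples: int = 201, mode: str = "max") -> np.ndarray:
    """Normalised pRF density over the visual field.

    Each usable fit contributes a unit-height Gaussian profile at its fitted
    centre/size.  In the default envelope mode (``"max"``) the map is the
    pointwise maximum profile, which is already in [0, 1] and independent of
    how many pRFs tile a region — a complete hemifield map scores near 1
    across the hemifield regardless of sampling density.  ``mode="sum"``
    accumulates profiles instead and divides by the map maximum; it reads as
    a true density but couples the binarisation threshold to the local
    crowding of pRF centres.
    """
    x0, y0, sigma = (np.asarray(a, dtype=float) for a in (x0, y0, sigma))
    if usable is not None:
        keep = np.asarray(usable, dtype=bool)
        x0, y0, sigma = x0[keep], y0[keep], sigma[keep]
    if x0.size == 0:
        raise ValueError("no usable pRF fits for the density map")
    _, _, X, Y = field_grid(max_ecc, grid_samples)
    dens = np.zeros_like(X)
    for xi, yi, si in zip(x0, y0, sigma):
        g = np.exp(-((X - xi) ** 2 + (Y - yi) ** 2) / (2.0 * si ** 2))
        if mode == "max":
            np.maximum(dens, g, out=dens)
        else:
            dens += g
    if mode == "max":
        return dens           # unit-height profiles: already in [0, 1]
    mx = dens.max()
    return dens / mx if mx > 0 else dens


def quadrant_coverage(density: np.ndarray, quad: QuadrantSpec,
                      threshold: float = 0.8,
                      max_ecc: float = 5.5) -> dict:
    """Percent of each hemifield sector covered at or above the threshold.

    The sector area is the set of field-grid points within ``max_ecc``; the
    covered area is its subset where density >= threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = density.shape[0]
    _, _, X, Y = field_grid(max_ecc, n)
    from .geometry import polar_angle

    ang = polar_angle(X, Y)
    ecc = np.hypot(X, Y)
    sec = quad.sector_of(ang)
    inside = ecc <= max_ecc
    out = {}
    for i, name in enumerate(quad.sectors):
        sel = inside & (sec == i)
        if not sel.any():
            raise ValueError(f"sector {name!r} contains no grid points")
        out[name] = 100.0 * float((density[sel] >= threshold).mean())
    return out


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def classify_completeness(percents: dict, cutoff: float = 20.0) -> dict:
    """Complete iff the percent, rounded half-up to a whole number, reaches
    the cutoff (so 19.4 % is incomplete and 19.5 % is complete at 20 %)."""
    out = {}
    for name, p in percents.items():
        if not 0 <= p <= 100:
            raise ValueError(f"percent out of range for {name!r}: {p}")
        out[name] = round_half_up(p) >= cutoff
    return out


def full_coverage_report(x0, y0, sigma, usable, quad: QuadrantSpec,
                         density_threshold: float = 0.8,
                         cutoff: float = 20.0, max_ecc: float = 5.5,
                         grid_samples: int = 201, mode: str = "max",
                         roi_name: str = "") -> CoverageReport:
    dens = prf_density(x0, y0, sigma, usable, max_ecc, grid_samples, mode)
    pct = quadrant_coverage(dens, quad, density_threshold, max_ecc)
    return CoverageReport(percent=pct,
                          complete=classify_completeness(pct, cutoff),
                          density_threshold=density_threshold,
                          cutoff_percent=cutoff, roi_name=roi_name)


def _principal_gradient_angle(rows, cols, values):
    """Orientation (radians) of the least-squares linear gradient of
    ``values`` over lattice positions; 0 if the field is constant."""
    A = np.column_stack([cols, rows, np.ones_like(cols, dtype=float)])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    gx, gy = coef[0], coef[1]
    if abs(gx) < 1e-12 and abs(gy) < 1e-12:
        return 0.0
    return float(np.arctan2(gy, gx))


def render_angle_map(rows, cols, angles, roi_mask=None) -> np.ndarray:
    """Grayscale image of an ROI's polar-angle map, gradient-aligned.

    Voxels live on an integer lattice (``rows``/``cols``); their polar
    angles are mapped linearly to luminance in [0, 1] over the ROI's angle
    range.  The lattice is rotated so the principal angle gradient runs
    along the image x-axis and voxels are re-binned at unit spacing
    (averaging where several land in one cell).  Excluded pixels are NaN.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if roi_mask is not None:
        keep = np.asarray(roi_mask, dtype=bool)
        rows, cols, angles = rows[keep], cols[keep], angles[keep]
    if rows.size < 4 or np.unique(rows).size < 2 or np.unique(cols).size < 2:
        raise ValueError("ROI smaller than a 2x2 lattice patch")
    lo, hi = angles.min(), angles.max()
    lum = np.zeros_like(angles) if hi == lo else (angles - lo) / (hi - lo)
    th = _principal_gradient_angle(rows, cols, angles)
    xr = cols * np.cos(th) + rows * np.sin(th)
    yr = -cols * np.sin(th) + rows * np.cos(th)
    ix = np.round(xr - xr.min()).astype(int)
    iy = np.round(yr - yr.min()).astype(int)
    h, w = iy.max() + 1, ix.max() + 1
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    np.add.at(acc, (iy, ix), lum)
    np.add.at(cnt, (iy, ix), 1.0)
    with np.errstate(invalid="ignore"):
        img = acc / cnt
    img[cnt == 0] = np.nan
    return img


def smoothness(image: np.ndarray) -> SmoothnessResult:
    """Map-smoothness statistic of a gradient-aligned grayscale image.

    Per-column mean luminance of included (non-NaN) pixels is min-max
    normalised across columns; the statistic is the total variation (sum of
    absolute successive differences) of that profile.  A clean monotone
    ramp spanning the range scores 1; rougher maps score higher.  A
    constant image has no angular gradient and scores 0 with a warning.
    """
    img = np.asarray(image, dtype=float)
    has = np.isfinite(img).any(axis=0)
    if has.sum() < 3:
        raise ValueError("need at least 3 usable image columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        colmean = np.nanmean(img[:, has], axis=0)
    lo, hi = colmean.min(), colmean.max()
    if hi == lo:
        warnings.warn("degenerate: no angular gradient across columns")
        return SmoothnessResult(column_profile=np.zeros_like(colmean),
                                smoothness=0.0, degenerate=True)
    prof = (colmean - lo) / (hi - lo)
    return SmoothnessResult(column_profile=prof,
                            smoothness=float(np.abs(np.diff(prof)).sum()))


def percent_smoother(s_a: float, s_b: float) -> float:
    """Signed percent by which map B is smoother than map A."""
    if s_a == 0:
        raise ValueError("reference smoothness is zero")
    return 100.0 * (s_a - s_b) / s_a
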