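"""Mean maps, correlation-sign voxel classes, venous eclipses and the flip
correction.

The chain implemented here mirrors the standard venous-artefact workflow:
normalised mean maps of the EPI signal reveal venous eclipses (elongated
low-intensity shadows of draining veins); correlating each voxel's
full-field time course with the HRF reference waveform splits voxels into
``positive`` and ``inverted`` by the sign of Pearson r; inverted time
courses are corrected by reflecting them about their own temporal mean,
which exactly negates r while leaving the mean map untouched; and
negatively correlated voxels beyond the stimulated eccentricity are
separated out as negative BOLD responses (NBRs) so neuronal suppression is
not confused with venous inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from .hemodynamics import ReferenceWaveform

POSITIVE = "positive"
INVERTED = "inverted"
NBR = "NBR"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class MeanMap:
    value: np.ndarray          # per voxel, max-normalised to (0, 1]
    normalising_max: float


def normalized_mean_map(series: np.ndarray) -> MeanMap:
    """Voxel-wise time average, divided by the maximum voxel average."""
    Y = np.atleast_2d(np.asarray(series, dtype=np.float64))
    if Y.shape[1] < 1 or not np.all(np.isfinite(Y)):
        raise ValueError("series must be non-empty and all-finite")
    means = Y.mean(axis=1)
    mx = float(means.max())
    if mx <= 0:
        raise ValueError("non-positive maximum mean: non-physical data")
    return MeanMap(value=means / mx, normalising_max=mx)


@dataclass
class CorrelationMap:
    """Pearson r of each voxel against the reference waveform, plus labels.

    A voxel is ``positive`` iff r >= 0 (a tie at exactly 0 counts as
    positive: flipping a zero-correlation voxel is a no-op in expectation).
    Zero-variance voxels get r = 0 and are flagged.
    """

    r: np.ndarray
    label: np.ndarray = field(default=None)
    flagged: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.label is None:
            self.label = np.where(self.r < 0, INVERTED, POSITIVE)
        if self.flagged is None:
            self.flagged = np.zeros(self.r.shape, dtype=bool)


def correlate_reference(series: np.ndarray,
                        reference: ReferenceWaveform | np.ndarray) -> CorrelationMap:
    """Per-voxel Pearson correlation with the reference waveform."""
    Y = np.atleast_2d(np.asarray(series, dtype=np.float64))
    ref = reference.values if isinstance(reference, ReferenceWaveform) else np.asarray(reference, float)
    if Y.shape[1] != ref.size:
        raise ValueError("series and reference lengths differ")
    rc = ref - ref.mean()
    rn = np.sqrt(rc @ rc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    yn = np.sqrt(np.einsum("vt,vt->v", Yc, Yc))
    flagged = yn <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ rc) / (yn * rn)
    r[flagged] = 0.0
    return CorrelationMap(r=r, flagged=flagged)


def flip_timecourses(series: np.ndarray, cmap: CorrelationMap,
                     threshold: float = 0.0) -> np.ndarray:
    """Flip (reflect about the temporal mean) negatively correlated voxels.

    A voxel is flipped iff its correlation is *strictly* stronger than the
    threshold in the negative direction, r < -threshold.  The reflection
    y' = 2 ybar - y is the unique pointwise correction that exactly negates
    Pearson r while preserving the voxel's mean (hence the mean map); it is
    an involution when applied twice with the same correlation map.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    Y = np.atleast_2d(np.asarray(series, dtype=np.float64))
    out = Y.copy()
    mask = cmap.r < -threshold
    if mask.any():
        m = Y[mask].mean(axis=1, keepdims=True)
        out[mask] = 2.0 * m - Y[mask]
    return out


class InvertedVoxelCorrector(BaseEstimator, TransformerMixin):
    """Transformer flavour of the flip correction.

    ``fit`` correlates the voxels of X with the reference waveform;
    ``transform`` flips the voxels whose fitted r is below ``-threshold``.
    The fitted correlation map is exposed as ``correlation_map_`` and the
    flip mask as ``flipped_``.
    """

    def __init__(self, reference=None, threshold: float = 0.0):
        self.reference = reference
        self.threshold = threshold

    def fit(self, X, y=None):
        if self.reference is None:
            raise ValueError("a reference waveform is required")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        self.correlation_map_ = correlate_reference(X, self.reference)
        self.flipped_ = self.correlation_map_.r < -self.threshold
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        return flip_timecourses(X, self.correlation_map_, self.threshold)


@dataclass
class EclipseROI:
    """Voxel-index set marking a venous eclipse on one depth layer."""

    indices: np.ndarray
    provenance: str = "detected"     # or "manual"
    layer: str = "integrated"

    @property
    def empty(self) -> bool:
        return self.indices.size == 0

    def mask(self, n_voxels: int) -> np.ndarray:
        m = np.zeros(n_voxels, dtype=bool)
        m[self.indices] = True
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n# layer: {self.layer}\n")
            for i in self.indices:
                fh.write(f"{int(i)}\n")

    @classmethod
    def load(cls, path) -> "EclipseROI":
        provenance, layer, idx = "manual", "integrated", []
        for line in open(path):
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                if k.strip() == "provenance":
                    provenance = v.strip()
                elif k.strip() == "layer":
                    layer = v.strip()
            elif line:
                idx.append(int(line))
        return cls(indices=np.array(idx, dtype=int), provenance=provenance,
                   layer=layer)


def detect_eclipse(mmap: MeanMap, shape: tuple[int, int],
                   intensity_quantile: float = 0.15, min_size: int = 20,
                   min_elongation: float = 2.0,
                   layer: str = "integrated") -> EclipseROI:
    """Automated surrogate for hand-drawn venous-eclipse ROIs.

    Voxels below the given intensity quantile of the normalised mean map are
    grouped into 4-connected components on the voxel lattice; components at
    least ``min_size`` voxels large and elongated (major/minor axis ratio at
    least ``min_elongation``, the shape signature of a vessel shadow) form
    the ROI.  An empty ROI is a valid "eclipse absent" outcome.
    """
    if not 0 < intensity_quantile < 1:
        raise ValueError("intensity_quantile must be in (0, 1)")
    img = np.asarray(mmap.value, dtype=float).reshape(shape)
    thr = np.quantile(img, intensity_quantile)
    low = img < thr
    labels = measure.label(low, connectivity=1)
    keep = np.zeros_like(low)
    for region in measure.regionprops(labels):
        if region.area < min_size:
            continue
        minor = region.axis_minor_length
        major = region.axis_major_length
        elong = np.inf if minor == 0 else major / minor
        if elong >= min_elongation:
            keep[labels == region.label] = True
    return EclipseROI(indices=np.flatnonzero(keep.ravel()),
                      provenance="detected", layer=layer)


class EclipseDetector(BaseEstimator):
    """Estimator flavour of :func:`detect_eclipse` (fit stores ``roi_``)."""

    def __init__(self, shape=None, intensity_quantile=0.15, min_size=20,
                 min_elongation=2.0, layer="integrated"):
        self.shape = shape
        self.intensity_quantile = intensity_quantile
        self.min_size = min_size
        self.min_elongation = min_elongation
        self.layer = layer

    def fit(self, X, y=None):
        """X: a MeanMap, or the per-voxel normalised mean values."""
        mmap = X if isinstance(X, MeanMap) else MeanMap(
            value=np.asarray(X, float), normalising_max=1.0)
        self.roi_ = detect_eclipse(mmap, self.shape, self.intensity_quantile,
                                   self.min_size, self.min_elongation,
                                   self.layer)
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.roi_.mask(np.asarray(
            X.value if isinstance(X, MeanMap) else X).size)


def classify_nbr_vs_inverted(cmap: CorrelationMap, ecc: np.ndarray,
                             stim_max: float = 5.5) -> np.ndarray:
    """Split negatively correlated voxels into inverted vs NBR by eccentricity.

    Negative-r voxels beyond the stimulated eccentricity are negative BOLD
    responses (neuronal suppression just outside the mapped field); those
    within it are inverted (venous artefact).  Voxels without an
    eccentricity estimate cannot be split and are flagged.
    """
    ecc = np.asarray(ecc, dtype=float)
    out = np.full(cmap.r.shape, POSITIVE, dtype=object)
    neg = cmap.r < 0
    missing = ~np.isfinite(ecc)
    if np.any(neg & missing):
        warnings.warn("negative voxels without eccentricity left unclassified")
    out[neg & ~missing & (ecc > stim_max)] = NBR
    out[neg & ~missing & (ecc <= stim_max)] = INVERTED
    out[neg & missing] = UNCLASSIFIABLE
    return out.astype(str)


def inverted_fraction_by_region(cmap: CorrelationMap,
                                regions: dict[str, np.ndarray]) -> pd.Series:
    """Percent of inverted (r < 0) voxels per named voxel set."""
    rows = {}
    for name, idx in regions.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"region {name!r} is empty")
        rows[name] = 100.0 * float((cmap.r[idx] < 0).sum()) / idx.size
    return pd.Series(rows, name="percent_inverted")
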