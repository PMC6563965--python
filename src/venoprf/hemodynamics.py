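"""Haemodynamic response modelling.

A canonical double-gamma haemodynamic response function (HRF) is used to
(i) build the reference waveform for the full-field control stimulus, and
(ii) convolve pRF model predictions with the BOLD response.  Convolution is
performed at a fine time step (default 0.1 s) with the volume-level neural
regressor held constant over each TR (zero-order hold), then resampled at
volume onsets.  This matters: with a 4 s ON block the cycle-averaged
response then peaks at 8 s after stimulus onset on the 2 s grid, whereas
naive TR-grid discrete convolution would put the peak at 6 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimulus import StimulusProtocol


@dataclass(frozen=True)
class HRFModel:
    """Double-gamma HRF parameterisation.

    ``peak_delay`` and ``undershoot_delay`` are the modes of the two gamma
    densities (seconds); ``undershoot_ratio`` is the relative amplitude of
    the subtracted undershoot.  The sampled kernel is normalised to unit
    peak, so downstream correlation analyses are scale-free.
    """

    peak_delay: float = 5.0
    undershoot_delay: float = 15.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    dt: float = 0.1

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("delays must be positive")
        if self.peak_delay >= self.undershoot_delay:
            raise ValueError("peak_delay must precede undershoot_delay")
        if self.kernel_length <= self.peak_delay:
            raise ValueError("kernel_length too short")


@dataclass(frozen=True)
class SampledKernel:
    values: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def hrf_kernel(model: HRFModel) -> SampledKernel:
    """Sample the double-gamma kernel at ``model.dt``, unit peak.

    Each gamma has unit scale so its mode equals ``shape - 1``; the kernel
    value at t = 0 is exactly 0.
    """
    model.validate()
    t = np.arange(0.0, model.kernel_length + model.dt / 2, model.dt)
    peak = stats.gamma.pdf(t, a=model.peak_delay + 1.0)
    under = stats.gamma.pdf(t, a=model.undershoot_delay + 1.0)
    k = peak - model.undershoot_ratio * under
    if k.max() <= 0:
        raise ValueError("degenerate kernel")
    return SampledKernel(values=k / k.max(), dt=model.dt)


def convolve_design(boxcar: np.ndarray, kernel: SampledKernel,
                    dt: float) -> np.ndarray:
    """Causal discrete convolution of a binary design with the kernel.

    ``boxcar`` must be sampled at the same dt as the kernel; the result is
    truncated to the boxcar's length.
    """
    boxcar = np.asarray(boxcar, dtype=float)
    if not np.all(np.isin(boxcar, (0.0, 1.0))):
        raise ValueError("boxcar must be binary")
    if abs(dt - kernel.dt) > 1e-12:
        raise ValueError(f"dt mismatch: design {dt} vs kernel {kernel.dt}")
    return np.convolve(boxcar, kernel.values)[: boxcar.size]


def convolve_regressor(neural: np.ndarray, tr: float,
                       model: HRFModel) -> np.ndarray:
    """HRF-convolve a volume-level neural time course.

    The regressor is upsampled by zero-order hold to the kernel's dt,
    convolved, and sampled back at volume onsets.  Works on 1-D
    (n_volumes,) or 2-D (n_series, n_volumes) input.
    """
    neural = np.asarray(neural, dtype=float)
    kernel = hrf_kernel(model)
    up = int(round(tr / model.dt))
    if abs(up * model.dt - tr) > 1e-9:
        raise ValueError("tr must be an integer multiple of the kernel dt")
    squeeze = neural.ndim == 1
    y = np.atleast_2d(neural)
    fine = np.repeat(y, up, axis=1)
    n_fine = fine.shape[1]
    # FFT convolution along time, truncated to scan length
    from scipy.signal import fftconvolve

    conv = fftconvolve(fine, kernel.values[None, :], axes=1)[:, :n_fine]
    out = conv[:, ::up]
    return out[0] if squeeze else out


@dataclass
class ReferenceWaveform:
    """Expected BOLD waveform for the full-field flash, one value per volume."""

    values: np.ndarray
    protocol_name: str
    tr: float
    zero_meaned: bool = True


def fullfield_boxcar(protocol: StimulusProtocol) -> np.ndarray:
    """Volume-level ON/OFF indicator for the retained full-field volumes."""
    if protocol.name != "fullfield":
        raise ValueError("boxcar defined for the fullfield protocol only")
    t = np.arange(protocol.n_retained) * protocol.tr
    return ((t % protocol.cycle_period) < protocol.on_duration).astype(float)


def reference_waveform(protocol: StimulusProtocol,
                       model: HRFModel | None = None) -> ReferenceWaveform:
    """HRF-convolved, zero-meaned full-field ON/OFF waveform on the TR grid.

    The reference is defined for the full-field control stimulus only; it is
    what voxel time courses are correlated against to label them positive or
    inverted.
    """
    if protocol.name != "fullfield":
        raise ValueError(
            "reference waveform is defined for the fullfield protocol only"
        )
    model = model or HRFModel()
    box = fullfield_boxcar(protocol)
    v = convolve_regressor(box, protocol.tr, model)
    v = v - v.mean()
    return ReferenceWaveform(values=v, protocol_name=protocol.name,
                             tr=protocol.tr)


@dataclass
class IRFEstimate:
    """Event-averaged block/impulse response of a voxel group.

    Mean and SEM are in percent signal change about each voxel's own run
    mean; the time axis is peristimulus time on the TR grid.
    """

    mean_response: np.ndarray
    sem: np.ndarray
    time_axis: np.ndarray
    time_to_peak: float
    n_voxels: int


def event_average_irf(series: np.ndarray, protocol: StimulusProtocol,
                      group: np.ndarray | list, window: float) -> IRFEstimate:
    """Average per-cycle epochs of the full-field response over a voxel group.

    Epochs are aligned to ON onsets; each voxel's time course is converted
    to percent signal change about its own mean, averaged over cycles, then
    over the group; SEM is computed over voxels.  ``time_to_peak`` is the
    latency of the extremum (maximum for predominantly positive responses,
    minimum for inverted ones) on the TR grid.
    """
    if protocol.name != "fullfield":
        raise ValueError("IRFs are computed from the fullfield protocol")
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("empty voxel group")
    if window > protocol.cycle_period:
        raise ValueError("window exceeds the stimulus cycle")
    Y = np.asarray(series, dtype=float)[group]
    mean = Y.mean(axis=1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero-mean voxel: percent signal change undefined")
    psc = 100.0 * (Y - mean) / mean
    w = int(round(window / protocol.tr))
    per_cycle = int(round(protocol.cycle_period / protocol.tr))
    onsets = np.arange(0, Y.shape[1] - w + 1, per_cycle)
    epochs = np.stack([psc[:, o:o + w] for o in onsets], axis=0)
    per_voxel = epochs.mean(axis=0)            # (n_voxels, w)
    mean_resp = per_voxel.mean(axis=0)
    sem = (per_voxel.std(axis=0, ddof=1) / np.sqrt(group.size)
           if group.size > 1 else np.zeros(w))
    t = np.arange(w) * protocol.tr
    i_ext = int(np.argmax(np.abs(mean_resp)))
    idx = int(np.argmax(mean_resp)) if mean_resp[i_ext] >= 0 else int(np.argmin(mean_resp))
    return IRFEstimate(mean_response=mean_resp, sem=sem, time_axis=t,
                       time_to_peak=float(t[idx]), n_voxels=int(group.size))
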