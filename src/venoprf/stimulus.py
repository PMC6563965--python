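"""Retinotopic mapping stimulus protocols and binary aperture movies.

Four protocols are modelled, matching a conventional travelling-wave plus
pRF-mapping session at 3 T (TR = 2 s, display radius 5.5 deg):

* ``bowtie``  — rotating double wedge, 15 cycles, 186 volumes (first 6 discarded);
* ``ring``    — expanding annulus, 12 cycles, 174 volumes (first 6 discarded);
* ``bar``     — drifting bar at 4 orientations x 2 directions (8 sweeps of
  40 s) with four 20 s blank blocks, 200 volumes, none discarded;
* ``fullfield`` — full-field flash, 12 cycles of 4 s ON / 16 s OFF,
  124 volumes (first 4 discarded); the control stimulus used to classify
  positive vs inverted responses.

Aperture movies are binarised stimulus masks on a square visual-field grid,
one frame per retained volume; the chequerboard carrier pattern is not
modelled because only the aperture enters the pRF forward model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import field_grid

STIMULUS_NAMES = ("bowtie", "ring", "bar", "fullfield")

#: Bar orientations in degrees. 115 is deliberate (stimulus was presented at
#: 0/45/90/115, not the conventional 135).
BAR_ORIENTATIONS = (0.0, 45.0, 90.0, 115.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and geometry of one mapping stimulus."""

    name: str
    tr: float = 2.0
    n_volumes_acquired: int = 0
    n_discard: int = 0
    n_cycles: int | None = None
    cycle_period: float | None = None  # seconds
    on_duration: float | None = None   # fullfield only
    off_duration: float | None = None  # fullfield only
    max_eccentricity: float = 5.5
    bar_sweep_duration: float = 40.0
    bar_orientations: tuple = BAR_ORIENTATIONS
    n_blank_blocks: int = 4
    blank_duration: float = 20.0

    @property
    def n_retained(self) -> int:
        return self.n_volumes_acquired - self.n_discard

    @property
    def duration(self) -> float:
        """Retained scan duration in seconds."""
        return self.n_retained * self.tr

    def validate(self) -> None:
        if self.name not in STIMULUS_NAMES:
            raise ValueError(
                f"unknown stimulus {self.name!r}; valid names: {STIMULUS_NAMES}"
            )
        if self.n_retained <= 0:
            raise ValueError("no retained volumes")
        if self.name == "fullfield":
            expected = self.n_cycles * (self.on_duration + self.off_duration)
            if abs(self.duration - expected) > 1e-9:
                raise ValueError("fullfield timing does not tile the scan")
        elif self.name == "bar":
            n_sweeps = 2 * len(self.bar_orientations)
            expected = (
                n_sweeps * self.bar_sweep_duration
                + self.n_blank_blocks * self.blank_duration
            )
            if abs(self.duration - expected) > 1e-9:
                raise ValueError("bar sweep/blank schedule does not tile the scan")
        elif self.n_cycles is not None and self.cycle_period is not None:
            if abs(self.duration - self.n_cycles * self.cycle_period) > 1e-9:
                raise ValueError("cycles do not tile the scan")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        d = yaml.safe_load(Path(path).read_text())
        d["bar_orientations"] = tuple(d.get("bar_orientations", BAR_ORIENTATIONS))
        return cls(**d)


_PUBLISHED = {
    # name: (acquired, discarded, cycles, cycle period [s])
    "bowtie": (186, 6, 15, 24.0),
    "ring": (174, 6, 12, 28.0),
    "fullfield": (124, 4, 12, 20.0),
}


def make_protocol(name: str, tr: float = 2.0) -> StimulusProtocol:
    """Return the published timing for one of the four mapping stimuli."""
    if name == "bar":
        p = StimulusProtocol(name="bar", tr=tr, n_volumes_acquired=200, n_discard=0)
    elif name in _PUBLISHED:
        acq, disc, cyc, per = _PUBLISHED[name]
        kw = {}
        if name == "fullfield":
            kw = dict(on_duration=4.0, off_duration=16.0)
        p = StimulusProtocol(
            name=name, tr=tr, n_volumes_acquired=acq, n_discard=disc,
            n_cycles=cyc, cycle_period=per, **kw,
        )
    else:
        raise ValueError(
            f"unknown stimulus {name!r}; valid names: {STIMULUS_NAMES}"
        )
    p.validate()
    return p


@dataclass
class ApertureMovie:
    """Binary stimulus aperture per retained volume on a visual-field grid."""

    frames: np.ndarray          # (n_volumes, n_samples, n_samples) bool
    degrees_per_sample: float
    grid_extent: float          # half-width; grid covers +-grid_extent
    timestamps: np.ndarray      # seconds, one per frame, 0 at first retained volume
    protocol_name: str
    tr: float
    xs: np.ndarray = field(repr=False, default=None)
    ys: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def coverage_fraction(self) -> np.ndarray:
        """Fraction of the stimulated disc that is ON, per frame."""
        X, Y = np.meshgrid(self.xs, self.ys)
        disc = (X ** 2 + Y ** 2) <= self.grid_extent ** 2
        return self.frames[:, disc].mean(axis=1)

    def save(self, path) -> None:
        """Write frames to a compressed array container with a YAML sidecar."""
        path = Path(path)
        np.savez_compressed(path, frames=self.frames.astype(np.uint8),
                            timestamps=self.timestamps, xs=self.xs, ys=self.ys)
        meta = {
            "degrees_per_sample": float(self.degrees_per_sample),
            "grid_extent": float(self.grid_extent),
            "protocol_name": self.protocol_name,
            "tr": float(self.tr),
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path) -> "ApertureMovie":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arr = np.load(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        return cls(frames=arr["frames"].astype(bool),
                   timestamps=arr["timestamps"], xs=arr["xs"], ys=arr["ys"],
                   **meta)


def _bar_schedule(protocol: StimulusProtocol):
    """Per-frame (kind, orientation, direction, sweep position in [0,1)).

    Sweeps run in presentation order orientation-major (each orientation in
    its two perpendicular directions) with a blank block after every second
    sweep.
    """
    frames_per_sweep = int(round(protocol.bar_sweep_duration / protocol.tr))
    frames_per_blank = int(round(protocol.blank_duration / protocol.tr))
    sched = []
    sweep_no = 0
    for ori in protocol.bar_orientations:
        for direction in (+1, -1):
            for f in range(frames_per_sweep):
                sched.append(("sweep", ori, direction, (f + 0.5) / frames_per_sweep))
            sweep_no += 1
            if sweep_no % 2 == 0:
                sched.extend([("blank", 0.0, 0, 0.0)] * frames_per_blank)
    return sched


def render_apertures(protocol: StimulusProtocol, grid_samples: int = 101,
                     wedge_width: float = 45.0, ring_duty: float = 0.25,
                     bar_width: float | None = None) -> ApertureMovie:
    """Render the binary aperture movie for a protocol.

    Parameters not fixed by the protocol timing are conventional defaults:
    the bowtie is a double wedge of ``wedge_width`` degrees per wedge
    rotating clockwise one revolution per cycle; the ring is an annulus of
    width ``ring_duty * max_eccentricity`` expanding from the centre once
    per cycle; the bar is ``bar_width`` wide (default 1/8 of the display
    width) and traverses the display in 40 s per sweep.
    """
    if grid_samples < 16:
        raise ValueError("grid_samples must be >= 16")
    protocol.validate()
    me = protocol.max_eccentricity
    if bar_width is None:
        bar_width = 2.0 * me / 8.0
    step = 2.0 * me / grid_samples
    if protocol.name == "bar" and step > bar_width:
        raise ValueError("grid too coarse to represent the bar aperture")
    if protocol.name == "ring" and step > ring_duty * me:
        raise ValueError("grid too coarse to represent the ring annulus")

    xs, ys, X, Y = field_grid(me, grid_samples)
    R = np.hypot(X, Y)
    disc = R <= me
    # polar angle CCW from the upper vertical meridian
    ANG = np.mod(np.degrees(np.arctan2(Y, X)) - 90.0, 360.0)

    n = protocol.n_retained
    frames = np.zeros((n, grid_samples, grid_samples), dtype=bool)
    t = np.arange(n) * protocol.tr

    if protocol.name == "fullfield":
        on = (t % protocol.cycle_period) < protocol.on_duration
        frames[on] = disc
    elif protocol.name == "bowtie":
        fpc = protocol.cycle_period / protocol.tr
        for i in range(n):
            phase = (i % fpc) / fpc
            centre = (-360.0 * phase) % 360.0  # clockwise rotation
            d = np.abs((ANG - centre + 90.0) % 180.0 - 90.0)
            frames[i] = disc & (d <= wedge_width / 2.0)
    elif protocol.name == "ring":
        fpc = protocol.cycle_period / protocol.tr
        width = ring_duty * me
        for i in range(n):
            phase = (i % fpc) / fpc
            r_in = phase * me
            frames[i] = disc & (R >= r_in) & (R < r_in + width)
    elif protocol.name == "bar":
        for i, (kind, ori, direction, pos) in enumerate(_bar_schedule(protocol)):
            if kind == "blank":
                continue
            th = np.radians(ori)
            # bar long axis at `ori` deg CCW from vertical; sweep along normal
            proj = X * np.cos(th) + Y * np.sin(th)
            centre = direction * (2.0 * pos - 1.0) * me
            frames[i] = disc & (np.abs(proj - centre) <= bar_width / 2.0)
    return ApertureMovie(frames=frames, degrees_per_sample=step, grid_extent=me,
                         timestamps=t, protocol_name=protocol.name,
                         tr=protocol.tr, xs=xs, ys=ys)


def discard_initial(series: np.ndarray, n: int,
                    timestamps: np.ndarray | None = None):
    """Drop the first ``n`` entries along the time axis (axis 0).

    Returns the trimmed series, or ``(series, timestamps)`` with timestamps
    re-zeroed to the first retained entry when timestamps are given.
    """
    series = np.asarray(series)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= series.shape[0]:
        raise ValueError(
            f"cannot discard {n} of {series.shape[0]} volumes: nothing left"
        )
    out = series[n:]
    if timestamps is None:
        return out
    ts = np.asarray(timestamps)[n:]
    return out, ts - ts[0]
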