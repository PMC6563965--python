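"""Synthetic cortical patches with venous artefact.

The generator emulates the statistical structure the analysis assumes, on a
schematic flattened cortical patch: a voxel lattice whose columns are
divided into strips for V1, V2, V3, hV4 and an extra-stimulus periphery,
each strip carrying a smooth retinotopic gradient (polar angle along rows,
eccentricity along columns) so that hV4 maps a full contralateral
hemifield.  Three cortical depth layers are simulated (2.5 mm and 1 mm
above the grey/white boundary, and the boundary itself); a spatially
contiguous, elongated venous eclipse is injected near the lower hV4 border
whose mean-intensity drop and inverted-response probability both decay with
depth, mirroring the physics of draining-vein artefact which is strongest
near the cortical surface.  Voxels in the periphery strip lie just beyond
the stimulated eccentricity and respond with negative BOLD responses
(suppression): strong, clean anticorrelated time courses at full mean
intensity, in contrast to the dim, noisier inverted voxels of the eclipse.

Forward model per voxel and layer (baseline b, amplitude beta, noise sd s):

    positive:  b * (1 - drop if in eclipse)  + beta * d(t) + N(0, s)
    inverted:  b * (1 - drop)                - beta * d(t) + N(0, s)
    NBR:       b                        - beta_nbr * D(t)  + N(0, s_nbr)

where d(t) is the voxel's HRF-convolved pRF overlap with the stimulus
aperture and D(t) the HRF-convolved whole-display coverage (the aggregate
drive behind suppression).  The depth-integrated series is the unweighted
mean over the three layers.  All randomness flows from the single spec
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import from_polar, sector_index
from .hemodynamics import HRFModel
from .prf import PredictionEngine
from .stimulus import ApertureMovie, make_protocol, render_apertures

LAYERS = ("d2.5mm", "d1mm", "grey_white")   # superficial -> deep
INTEGRATED = "integrated"
AREAS = ("V1", "V2", "V3", "hV4", "periphery")
_AREA_FRACTIONS = (0.23, 0.23, 0.24, 0.20, 0.10)

MAPPING_PROTOCOLS = ("bowtie", "ring", "bar")
SCENARIO_NAMES = ("default", "missing_lower", "subject10")


@dataclass
class PatchSpec:
    """Everything the generator needs, including the ground-truth dials."""

    rows: int = 30
    cols: int = 30
    max_ecc: float = 5.5
    ecc_range: tuple = (0.25, 5.25)
    nbr_band: tuple = (5.75, 7.0)
    angle_range: tuple = (5.0, 175.0)
    hemifield: str = "left"
    # eclipse geometry: (row_start, row_stop, col_start, col_stop); None for
    # the default elongated band near the lower hV4 border, or "none"
    eclipse_box: tuple | None | str = None
    inversion_prob: tuple = (0.8, 0.5, 0.2)     # per layer, superficial->deep
    intensity_drop: tuple = (0.45, 0.3, 0.1)    # per layer, superficial->deep
    baseline: float = 100.0
    baseline_sd: float = 8.0      # spatial EPI-intensity heterogeneity
    beta: float = 2.0
    noise_sd: float = 1.0
    nbr_beta: float = 1.5
    nbr_noise_sd: float = 0.5
    sigma_intercept: float = 0.3                # pRF size vs eccentricity
    sigma_slope: float = 0.2
    missing_lower: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 4 or self.cols < 5:
            raise ValueError("lattice too small")
        for name, t in (("inversion_prob", self.inversion_prob),
                        ("intensity_drop", self.intensity_drop)):
            if len(t) != len(LAYERS) or any(np.diff(t) > 0):
                raise ValueError(
                    f"{name} must be non-increasing superficial -> deep")
        if self.nbr_band[0] <= self.max_ecc:
            raise ValueError("nbr_band must lie wholly outside max_ecc")
        box = self._resolve_eclipse()
        if box is not None:
            r0, r1, c0, c1 = box
            if not (0 <= r0 < r1 <= self.rows and 0 <= c0 < c1 <= self.cols):
                raise ValueError("eclipse box outside the lattice")

    def _resolve_eclipse(self):
        if self.eclipse_box == "none":
            return None
        if self.eclipse_box is not None:
            return tuple(self.eclipse_box)
        # default: 3-row band spanning V2..hV4 columns, near the lower
        # (large polar angle) rows where the lower hV4 border lives
        bounds = area_column_bounds(self.cols)
        r1 = self.rows - 4
        return (max(0, r1 - 3), r1, bounds[1], bounds[4])

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k in ("ecc_range", "nbr_band", "angle_range", "inversion_prob",
                  "intensity_drop"):
            d[k] = list(d[k])
        if isinstance(d["eclipse_box"], tuple):
            d["eclipse_box"] = list(d["eclipse_box"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PatchSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("ecc_range", "nbr_band", "angle_range", "inversion_prob",
                  "intensity_drop"):
            d[k] = tuple(d[k])
        if isinstance(d.get("eclipse_box"), list):
            d["eclipse_box"] = tuple(d["eclipse_box"])
        return cls(**d)


def area_column_bounds(cols: int) -> list[int]:
    """Column boundaries of the five area strips (length 6, 0..cols)."""
    cum = np.cumsum((0.0,) + _AREA_FRACTIONS)
    return [int(round(f * cols)) for f in cum]


@dataclass
class CorticalPatch:
    """Voxel lattice with ground truth. Voxel order is row-major."""

    spec: PatchSpec
    row: np.ndarray
    col: np.ndarray
    area: np.ndarray            # str per voxel
    x0: np.ndarray
    y0: np.ndarray
    sigma: np.ndarray
    ecc: np.ndarray
    angle: np.ndarray
    eclipse_mask: np.ndarray
    classes: dict               # layer (incl. integrated) -> str array
    baseline_map: np.ndarray = None   # per-voxel EPI baseline intensity

    @property
    def n_voxels(self) -> int:
        return self.row.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.spec.rows, self.spec.cols)

    def area_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.area == name)

    def ground_truth(self) -> pd.DataFrame:
        frames = []
        for layer, cls in self.classes.items():
            frames.append(pd.DataFrame({
                "voxel": np.arange(self.n_voxels),
                "row": self.row, "col": self.col, "layer": layer,
                "area": self.area, "x0": self.x0, "y0": self.y0,
                "sigma": self.sigma, "eccentricity": self.ecc,
                "polar_angle": self.angle, "class": cls,
                "in_eclipse": self.eclipse_mask,
            }))
        return pd.concat(frames, ignore_index=True)


def make_retinotopic_patch(spec: PatchSpec) -> CorticalPatch:
    """Lay out ground-truth retinotopy, the eclipse, and voxel classes.

    Polar angle varies smoothly along rows (the same gradient in every
    strip, so neighbouring voxels map neighbouring field positions) and
    eccentricity along the columns of each strip; pRF size grows linearly
    with eccentricity.  Inversion inside the eclipse is Bernoulli per layer
    with the spec's depth-decaying probabilities; the depth-integrated
    class of a voxel is inverted when the majority of its layers are
    (layer amplitudes are equal, so the sign of the summed response is the
    sign of the majority).
    """
    spec.validate()
    R, C = spec.rows, spec.cols
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    row, col = rr.ravel(), cc.ravel()
    n = row.size

    bounds = area_column_bounds(C)
    area = np.empty(n, dtype=object)
    u = np.zeros(n)                      # within-strip column fraction
    # golden-ratio stagger of eccentricity across rows: real pRF centres
    # scatter rather than sitting on iso-eccentricity arcs, and the density
    # map needs quasi-uniform tiling of the hemifield
    stagger = (row * 0.6180339887498949) % 1.0 - 0.5
    for i, name in enumerate(AREAS):
        c0, c1 = bounds[i], bounds[i + 1]
        sel = (col >= c0) & (col < c1)
        area[sel] = name
        u[sel] = (col[sel] - c0 + 0.5 + stagger[sel]) / (c1 - c0)

    a0, a1 = spec.angle_range
    angle = a0 + (row + 0.5) / R * (a1 - a0)
    if spec.hemifield == "right":
        angle = 360.0 - angle
    e0, e1 = spec.ecc_range
    ecc = e0 + u * (e1 - e0)
    per = area == "periphery"
    ecc[per] = spec.nbr_band[0] + u[per] * (spec.nbr_band[1] - spec.nbr_band[0])
    x0, y0 = from_polar(angle, ecc)
    sigma = spec.sigma_intercept + spec.sigma_slope * ecc

    eclipse = np.zeros(n, dtype=bool)
    box = spec._resolve_eclipse()
    if box is not None:
        r0, r1, c0, c1 = box
        eclipse = ((row >= r0) & (row < r1) & (col >= c0) & (col < c1))
        eclipse &= ~per                  # the eclipse shadows mapped cortex

    silent = np.zeros(n, dtype=bool)
    if spec.missing_lower:
        lower = sector_index(angle, spec.hemifield) == 3
        silent = (area == "hV4") & lower

    rng = np.random.default_rng([int(spec.seed), 0])
    classes = {}
    inv_draw = {}
    for layer, p in zip(LAYERS, spec.inversion_prob):
        inv = eclipse & (rng.random(n) < p)
        inv_draw[layer] = inv
        cls = np.full(n, "positive", dtype=object)
        cls[inv] = "inverted"
        cls[per] = "NBR"
        cls[silent] = "silent"
        classes[layer] = cls.astype(str)
    n_inv = np.sum([inv_draw[l] for l in LAYERS], axis=0)
    cls = np.full(n, "positive", dtype=object)
    cls[n_inv >= 2] = "inverted"
    cls[per] = "NBR"
    cls[silent] = "silent"
    classes[INTEGRATED] = cls.astype(str)

    # spatial EPI-intensity heterogeneity (coil profile, anatomy); a vascular
    # property of the voxel, hence shared across depth layers and protocols
    baseline_map = spec.baseline + spec.baseline_sd * rng.standard_normal(n)
    baseline_map = np.clip(baseline_map, 0.2 * spec.baseline, None)

    return CorticalPatch(spec=spec, row=row, col=col, area=area.astype(str),
                         x0=x0, y0=y0, sigma=sigma, ecc=ecc, angle=angle,
                         eclipse_mask=eclipse, classes=classes,
                         baseline_map=baseline_map)


def simulate_bold(patch: CorticalPatch, movies: dict,
                  hrf: HRFModel | None = None,
                  rng: np.random.Generator | None = None) -> dict:
    """Simulate per-layer BOLD series for each protocol.

    Returns ``{protocol: {layer: (n_voxels, n_volumes) array}}`` with an
    extra ``integrated`` layer equal to the mean over the three depth
    layers.  Identical seeds give bit-identical output.
    """
    if not movies:
        raise ValueError("at least one rendered protocol movie is required")
    spec = patch.spec
    hrf = hrf or HRFModel()
    rng = rng or np.random.default_rng([int(spec.seed), 1])
    out = {}
    for name, movie in movies.items():
        engine = PredictionEngine(movie, hrf)
        n, T = patch.n_voxels, movie.n_frames
        drive = np.zeros((n, T))
        prf_driven = ~np.isin(patch.area, ["periphery"])
        for v in np.flatnonzero(prf_driven):
            drive[v] = engine.drive(patch.x0[v], patch.y0[v], patch.sigma[v])
        # aggregate display drive behind NBR suppression
        X, Y = np.meshgrid(movie.xs, movie.ys)
        disc = ((X ** 2 + Y ** 2) <= movie.grid_extent ** 2).ravel()
        w = disc.astype(float) / disc.sum()
        nbr_drive = engine.conv @ w
        # responses modulate about the baseline: the time-mean of the EPI
        # signal carries the vascular intensity information, not the
        # stimulus duty cycle
        drive = drive - drive.mean(axis=1, keepdims=True)
        nbr_drive = nbr_drive - nbr_drive.mean()

        layers = {}
        for layer, drop in zip(LAYERS, spec.intensity_drop):
            cls = patch.classes[layer]
            Yv = np.empty((n, T))
            base = patch.baseline_map.copy()
            base[patch.eclipse_mask] *= (1.0 - drop)
            sign = np.where(cls == "inverted", -1.0, 1.0)
            amp = np.where(cls == "silent", 0.0, spec.beta) * sign
            Yv[:] = base[:, None] + amp[:, None] * drive
            noise_sd = np.full(n, spec.noise_sd)
            is_nbr = cls == "NBR"
            Yv[is_nbr] = (base[is_nbr, None]
                          - spec.nbr_beta * nbr_drive[None, :])
            noise_sd[is_nbr] = spec.nbr_noise_sd
            Yv += rng.normal(0.0, 1.0, size=(n, T)) * noise_sd[:, None]
            layers[layer] = Yv
        layers[INTEGRATED] = np.mean([layers[l] for l in LAYERS], axis=0)
        out[name] = layers
    return out


@dataclass
class SyntheticBundle:
    """A generated patch plus its rendered stimuli and simulated series."""

    spec: PatchSpec
    patch: CorticalPatch
    movies: dict                 # protocol -> ApertureMovie
    series: dict                 # protocol -> layer -> array
    hrf: HRFModel = field(default_factory=HRFModel)

    def mapping_series(self, layer: str = INTEGRATED) -> np.ndarray:
        """Concatenated bowtie+ring+bar series for joint pRF fitting."""
        return np.concatenate(
            [self.series[p][layer] for p in MAPPING_PROTOCOLS
             if p in self.series], axis=1)

    def mapping_movies(self) -> list[ApertureMovie]:
        return [self.movies[p] for p in MAPPING_PROTOCOLS
                if p in self.movies]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spec.to_yaml(out / "spec.yaml")
        self.patch.ground_truth().to_csv(out / "ground_truth.csv", index=False)
        arrays = {f"{p}__{layer}": arr
                  for p, layers in self.series.items()
                  for layer, arr in layers.items()}
        np.savez_compressed(out / "series.npz", **arrays)
        for p, movie in self.movies.items():
            movie.save(out / f"apertures_{p}.npz")

    @classmethod
    def load(cls, out_dir) -> "SyntheticBundle":
        out = Path(out_dir)
        spec = PatchSpec.from_yaml(out / "spec.yaml")
        patch = make_retinotopic_patch(spec)
        arrs = np.load(out / "series.npz")
        series: dict = {}
        for key in arrs.files:
            p, layer = key.split("__")
            series.setdefault(p, {})[layer] = arrs[key]
        movies = {p: ApertureMovie.load(out / f"apertures_{p}.npz")
                  for p in series}
        return cls(spec=spec, patch=patch, movies=movies, series=series)


def _render_all(protocol_names, grid_samples):
    return {name: render_apertures(make_protocol(name), grid_samples)
            for name in protocol_names}


def make_bundle(spec: PatchSpec, grid_samples: int = 51,
                protocols=("bowtie", "ring", "bar", "fullfield"),
                hrf: HRFModel | None = None) -> SyntheticBundle:
    hrf = hrf or HRFModel()
    patch = make_retinotopic_patch(spec)
    movies = _render_all(protocols, grid_samples)
    series = simulate_bold(patch, movies, hrf)
    return SyntheticBundle(spec=spec, patch=patch, movies=movies,
                           series=series, hrf=hrf)


def scenario_default(seed: int = 0, grid_samples: int = 51,
                     **overrides) -> SyntheticBundle:
    """The default study conditions: 30x30 patch, depth-decaying eclipse."""
    return make_bundle(PatchSpec(seed=seed, **overrides), grid_samples)


def scenario_missing_lower(seed: int = 0, grid_samples: int = 51,
                           **overrides) -> SyntheticBundle:
    """Incomplete-without-artefact control: lower-sector hV4 pRFs removed,
    no eclipse injected."""
    overrides.setdefault("eclipse_box", "none")
    return make_bundle(PatchSpec(seed=seed, missing_lower=True, **overrides),
                       grid_samples)


def scenario_subject10(seed: int = 0, rows: int = 24, cols: int = 24,
                       grid_samples: int = 51,
                       **overrides) -> SyntheticBundle:
    """A complete hV4 hemifield whose lower-sector voxels are all rendered
    inverted, so the measured map classifies incomplete before correction
    and complete after flipping and refitting."""
    bounds = area_column_bounds(cols)
    a0, a1 = overrides.get("angle_range", (5.0, 175.0))
    # rows whose polar angle falls in the lower 45-degree sector
    row_angles = a0 + (np.arange(rows) + 0.5) / rows * (a1 - a0)
    lower_rows = np.flatnonzero(row_angles > 135.0)
    spec = PatchSpec(rows=rows, cols=cols, seed=seed,
                     eclipse_box=(int(lower_rows[0]), rows,
                                  bounds[3], bounds[4]),
                     inversion_prob=(1.0, 1.0, 1.0), **overrides)
    return make_bundle(spec, grid_samples)


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the three standard scenarios at test scale to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"not a writable directory: {out_dir}")
    bundles = {
        "default": scenario_default(seed),
        "missing_lower": scenario_missing_lower(seed),
        "subject10": scenario_subject10(seed),
    }
    for name, bundle in bundles.items():
        bundle.save(out / name)
    return bundles
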