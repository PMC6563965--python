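"""End-to-end before/after-correction analysis.

``run_pipeline`` chains the full workflow on a synthetic scenario or on a
real 4-D NIfTI series: normalised mean map -> correlation against the
full-field reference -> venous-eclipse ROI (detected or supplied) -> flip
correction -> pRF fits of the original and corrected series -> quadrant
coverage, map smoothness, inverted-voxel fractions, and the
coverage-vs-eclipse congruence label.  Every run echoes its configuration
and seed next to its outputs and is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import polar_angle
from .hemodynamics import HRFModel, reference_waveform
from .map_metrics import (QuadrantSpec, full_coverage_report, percent_smoother,
                          render_angle_map, smoothness)
from .prf import PRFMapper
from .stimulus import make_protocol
from .synthetic import (INTEGRATED, SyntheticBundle, scenario_default,
                        scenario_missing_lower, scenario_subject10)
from .voxel_classes import (EclipseROI, correlate_reference, detect_eclipse,
                            flip_timecourses, inverted_fraction_by_region,
                            normalized_mean_map)

log = logging.getLogger("venoprf.pipeline")

SCENARIOS = {
    "default": scenario_default,
    "missing_lower": scenario_missing_lower,
    "subject10": scenario_subject10,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    scenario: str = "default"            # synthetic scenario name, or "nifti"
    nifti_series: str | None = None
    nifti_mask: str | None = None
    eclipse_roi_file: str | None = None  # manual ROI; else automatic detection
    seed: int = 0
    tr: float = 2.0
    hrf: dict = field(default_factory=dict)
    flip_threshold: float = 0.0
    density_threshold: float = 0.8
    completeness_cutoff: float = 20.0
    ve_floor: float = 0.1
    amplitude: str = "nonnegative"
    eclipse_quantile: float = 0.15
    eclipse_min_size: int = 20
    eclipse_min_elongation: float = 2.0
    layer: str = INTEGRATED
    aperture_grid: int = 51
    out_dir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.density_threshold < 1:
            raise ValueError("density_threshold must be in (0, 1)")
        if self.flip_threshold < 0:
            raise ValueError("flip_threshold must be non-negative")
        if not 0 <= self.ve_floor < 1:
            raise ValueError("ve_floor must be in [0, 1)")
        if self.scenario != "nifti" and self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: "
                f"{sorted(SCENARIOS)} or 'nifti'")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Everything the analysis measures, before and after correction."""

    config: dict
    coverage_before: dict        # roi -> {percent, complete}
    coverage_after: dict
    smoothness_before: float
    smoothness_after: float
    percent_smoother: float
    inverted_fractions: dict     # area -> percent (and per-layer table)
    n_flipped: int
    eclipse: dict                # {present, n_voxels, provenance}
    congruence: str              # "congruent" | "incongruent"

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s


def congruence_label(lower_complete: bool, eclipse_present: bool) -> str:
    """Coverage-vs-eclipse pairing logic.

    A hemisphere is *incongruent* when the lower-quadrant completeness
    contradicts the venous-eclipse evidence: incomplete without an eclipse,
    or complete despite one.
    """
    incong = (not lower_complete and not eclipse_present) or \
             (lower_complete and eclipse_present)
    return "incongruent" if incong else "congruent"


def load_nifti_series(path, mask_path, tr_override: float | None = None):
    """Extract a masked voxel x volume matrix from a 4-D NIfTI image.

    Voxels are ordered by ascending linear index of the array transposed to
    (z, y, x) — x varies fastest — which keeps the ordering stable across
    runs and platforms.  Returns (series, voxel coordinates (i, j, k), tr).
    The TR is read from the header and falls back to ``tr_override`` (with
    a warning) when the header value is absent or non-positive.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D series, got shape {data.shape}")
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match series {data.shape[:3]}")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    zyx_order = np.argsort(
        np.ravel_multi_index(np.nonzero(mask)[::-1], mask.shape[::-1]))
    ijk = np.column_stack(np.nonzero(mask))[zyx_order]
    series = data[ijk[:, 0], ijk[:, 1], ijk[:, 2], :].astype(np.float64)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        if tr_override is None:
            raise ValueError("TR absent from header and no override given")
        log.warning("TR absent from NIfTI header; using configured %.3f s",
                    tr_override)
        tr = tr_override
    return series, ijk, tr


def write_series_nifti(path, series: np.ndarray, ijk: np.ndarray,
                       shape3, tr: float) -> None:
    """Inverse of :func:`load_nifti_series` for round-tripping bundles."""
    import nibabel as nib

    vol = np.zeros(tuple(shape3) + (series.shape[1],), dtype=np.float32)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = series
    img = nib.Nifti1Image(vol, np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:           # noqa: BLE001 - stage diagnostics
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig,
                 bundle: SyntheticBundle | None = None) -> RunReport:
    """Execute the full before/after-correction analysis.

    ``bundle`` may be supplied directly (e.g. a pre-generated or loaded
    synthetic bundle); otherwise the configured scenario is generated from
    the config seed.  Real-data (NIfTI) runs require a lattice-free subset
    of the analysis and a manual eclipse ROI; the synthetic path exercises
    every stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    hrf = HRFModel(**config.hrf)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    @_stage("inputs")
    def _inputs():
        if bundle is not None:
            return bundle
        if config.scenario == "nifti":
            raise ValueError(
                "NIfTI ingestion requires load_nifti_series plus a manual "
                "ROI workflow; supply a bundle for lattice analyses")
        return SCENARIOS[config.scenario](
            seed=config.seed, grid_samples=config.aperture_grid)

    bdl = _inputs()
    patch = bdl.patch
    layer = config.layer

    @_stage("mean_map")
    def _mean():
        return normalized_mean_map(bdl.series["fullfield"][layer])

    mmap = _mean()

    @_stage("correlation")
    def _corr():
        ref = reference_waveform(make_protocol("fullfield"), hrf)
        return correlate_reference(bdl.series["fullfield"][layer], ref)

    cmap = _corr()

    @_stage("eclipse")
    def _eclipse():
        if config.eclipse_roi_file:
            return EclipseROI.load(config.eclipse_roi_file)
        return detect_eclipse(mmap, patch.shape, config.eclipse_quantile,
                              config.eclipse_min_size,
                              config.eclipse_min_elongation, layer=layer)

    roi = _eclipse()

    @_stage("flip")
    def _flip():
        Y = bdl.mapping_series(layer)
        return Y, flip_timecourses(Y, cmap, config.flip_threshold)

    Y, Yc = _flip()
    n_flipped = int((cmap.r < -config.flip_threshold).sum())
    log.info("flipped %d of %d voxels", n_flipped, cmap.r.size)

    @_stage("prf_fits")
    def _fits():
        movies = bdl.mapping_movies()
        hv4 = patch.area_indices("hV4")
        before = PRFMapper(movies=movies, hrf=hrf, amplitude=config.amplitude,
                           ve_floor=config.ve_floor).fit(Y[hv4])
        after = PRFMapper(movies=movies, hrf=hrf, amplitude=config.amplitude,
                          ve_floor=config.ve_floor,
                          corrected=True).fit(Yc[hv4])
        return hv4, before, after

    hv4, fit_before, fit_after = _fits()

    @_stage("metrics")
    def _metrics():
        quad = QuadrantSpec(hemifield=patch.spec.hemifield)
        reports = {}
        for tag, m in (("before", fit_before), ("after", fit_after)):
            rep = full_coverage_report(
                m.x0_, m.y0_, m.sigma_, m.usable_, quad,
                config.density_threshold, config.completeness_cutoff,
                max_ecc=patch.spec.max_ecc, roi_name="hV4")
            reports[tag] = {"percent": rep.percent, "complete": rep.complete}
        smooth = {}
        for tag, m in (("before", fit_before), ("after", fit_after)):
            img = render_angle_map(patch.row[hv4], patch.col[hv4],
                                   polar_angle(m.x0_, m.y0_), m.usable_)
            smooth[tag] = smoothness(img).smoothness
        regions = {a: patch.area_indices(a) for a in
                   ("V1", "V2", "V3", "hV4") if (patch.area == a).any()}
        fractions = {"area": inverted_fraction_by_region(cmap, regions).to_dict()}
        if not roi.empty:
            per_layer = {}
            for lname in ("d2.5mm", "d1mm", "grey_white"):
                ref = reference_waveform(make_protocol("fullfield"), hrf)
                cm_l = correlate_reference(bdl.series["fullfield"][lname], ref)
                per_layer[lname] = inverted_fraction_by_region(
                    cm_l, {"eclipse": roi.indices}).to_dict()["eclipse"]
            fractions["eclipse_by_layer"] = per_layer
        return reports, smooth, fractions

    reports, smooth, fractions = _metrics()
    lower_complete = bool(reports["before"]["complete"]["lower"])
    report = RunReport(
        config=dataclasses.asdict(config),
        coverage_before=reports["before"], coverage_after=reports["after"],
        smoothness_before=smooth["before"], smoothness_after=smooth["after"],
        percent_smoother=percent_smoother(smooth["before"], smooth["after"]),
        inverted_fractions=fractions, n_flipped=n_flipped,
        eclipse={"present": not roi.empty, "n_voxels": int(roi.indices.size),
                 "provenance": roi.provenance},
        congruence=congruence_label(lower_complete, not roi.empty),
    )

    if out is not None:
        report.to_json(out / "report.json")
        fit_before.fits_.to_csv(out / "prf_fits_original.csv", index=False)
        fit_after.fits_.to_csv(out / "prf_fits_corrected.csv", index=False)
        pd.DataFrame({"voxel": np.arange(cmap.r.size), "r": cmap.r,
                      "label": cmap.label,
                      "mean_map": mmap.value}).to_csv(
            out / "voxel_classes.csv", index=False)
        roi.save(out / "eclipse_roi.txt")
    return report
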